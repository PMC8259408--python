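"""Neutral-evolution null model and one-sided p-values.

The null hypothesis is neutral evolution of the whole ligand family: a
random root sequence evolves along the family phylogeny under the WAG
empirical substitution model (no selection, no indels), preserving the
ortholog/paralog structure of the tree.  Each replicate is pushed through
the same component pipeline as real data, the per-site partial scores are
pooled across replicates into four background distributions, and a normal
is fitted to each.  A site's partial score is then tested one-sidedly
against the tail in which it would *increase* the combined score, so that
universally constrained positions (disulfide cysteines being the classic
case) do not reach significance through the paralog-divergence component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .alignio import AMINO_ACIDS, Alignment, species_tagger
from .conservation import ConservationConfig
from .coevolution import MIConfig
from .dirpred_core import compute_components
from .exceptions import ConfigError, DegenerateInputError, IdentityError, InputError

#: Residue order used by PAML-style .dat model files.
PAML_ORDER = "ARNDCQEGHILKMFPSTWYV"

COMPONENTS = ("I", "II", "III", "IV")


@dataclass
class SubstitutionModel:
    """A reversible 20-state substitution model.

    ``exchangeabilities`` is the symmetric matrix S (zero diagonal) and
    ``pi`` the equilibrium frequencies, both in canonical (alphabetical)
    residue order.  The rate matrix Q_ij = S_ij pi_j is rescaled so that
    one unit of branch length equals one expected substitution per site.
    """

    exchangeabilities: np.ndarray
    pi: np.ndarray
    name: str = "custom"
    Q: np.ndarray = field(init=False, repr=False)
    _eig: tuple = field(init=False, repr=False)

    def __post_init__(self) -> None:
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        if S.shape != (20, 20) or not np.allclose(S, S.T):
            raise ConfigError("exchangeabilities must be a symmetric 20x20 matrix")
        if (S < 0).any() or (pi <= 0).any():
            raise ConfigError("exchangeabilities and frequencies must be positive")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -float(np.sum(pi * np.diag(Q)))
        Q /= scale
        self.pi = pi
        self.Q = Q
        # symmetrize: B = D^{1/2} Q D^{-1/2} is symmetric for reversible Q
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        B = (B + B.T) / 2.0
        w, V = np.linalg.eigh(B)
        self._eig = (w, V, sq)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) via the eigendecomposition of the symmetrized
        generator; rows renormalized to kill ~1e-16 drift."""
        if not np.isfinite(t) or t < 0:
            raise ConfigError(f"branch length must be finite and >= 0, got {t}")
        w, V, sq = self._eig
        P = (V * np.exp(w * t)) @ V.T
        P = P / sq[:, None] * sq[None, :]
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)

    def expected_difference(self, t: float) -> float:
        """Probability that the states at the two ends of a branch of
        length t differ: 1 - sum_i pi_i P_ii(t)."""
        P = self.transition_matrix(t)
        return 1.0 - float(np.sum(self.pi * np.diag(P)))


def load_wag() -> SubstitutionModel:
    """The WAG model from the packaged PAML-format data file."""
    text = resources.files("dirpred.data").joinpath("wag.dat").read_text()
    rows = [
        [float(v) for v in ln.split()]
        for ln in text.splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    tri, freqs = rows[:-1], rows[-1]
    S_paml = np.zeros((20, 20))
    for i, row in enumerate(tri, start=1):
        S_paml[i, : len(row)] = row
    S_paml = S_paml + S_paml.T
    # remap PAML residue order to the canonical alphabetical order
    perm = [PAML_ORDER.index(a) for a in AMINO_ACIDS]
    S = S_paml[np.ix_(perm, perm)]
    pi = np.array(freqs)[perm]
    return SubstitutionModel(S, pi, name="WAG")


@dataclass
class PhyloTree:
    """A rooted tree with branch lengths plus a partition of its leaves
    into paralog groups."""

    tree: dendropy.Tree
    groups: dict[str, str]  # leaf label -> paralog group

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def group_leaves(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for label in sorted(self.leaf_labels):
            out.setdefault(self.groups[label], []).append(label)
        return {g: out[g] for g in sorted(out)}


def parse_newick(
    source: str | Path,
    groups: Mapping[str, str] | None = None,
    default_branch_length: float | None = None,
) -> PhyloTree:
    """Parse a rooted newick tree with branch lengths.

    ``source`` is a path or a newick string.  ``groups`` maps leaf
    labels to paralog groups; when omitted, the first underscore token
    of each leaf label is used.  Missing branch lengths raise unless a
    default is supplied.  Underscores in labels are preserved (no
    newick-space unquoting surprises).
    """
    text = str(source)
    if not text.lstrip().startswith("("):
        path = Path(source)
        if not path.exists():
            raise InputError(f"cannot read tree file {path}")
        text = path.read_text()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            rooting="default-rooted",
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise IdentityError(f"duplicate leaf labels in tree: {exc}") from None
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise IdentityError(f"duplicate leaf labels: {dup}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            if default_branch_length is None:
                raise InputError("tree has branches without lengths and no default")
            edge.length = default_branch_length
        if edge.length < 0:
            raise InputError(f"negative branch length {edge.length}")
    if groups is None:
        groups = {label: label.split("_", 1)[0] for label in labels}
    else:
        groups = dict(groups)
        missing = [l for l in labels if l not in groups]
        if missing:
            raise ConfigError(f"leaves without a paralog group: {missing}")
    return PhyloTree(tree, {l: groups[l] for l in labels})


def simulate_evolution(
    tree: PhyloTree | dendropy.Tree,
    model: SubstitutionModel,
    length: int,
    seed: int | np.random.Generator = 0,
) -> dict[str, str]:
    """Evolve a random root sequence down the tree.

    The root is drawn site-independently from the model's equilibrium
    frequencies; along each branch of length t every site transitions
    independently with matrix exp(Qt).  Returns one ungapped sequence of
    exactly ``length`` residues per leaf, keyed by leaf label.
    """
    if length < 1:
        raise ConfigError("length must be >= 1")
    dtree = tree.tree if isinstance(tree, PhyloTree) else tree
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    states: dict[int, np.ndarray] = {}
    root = dtree.seed_node
    states[id(root)] = rng.choice(20, size=length, p=model.pi)
    leaves: dict[str, str] = {}
    for node in dtree.preorder_node_iter():
        if node is root:
            parent_states = states[id(root)]
        else:
            parent_states = states[id(node)]
        if node.is_leaf():
            leaves[node.taxon.label] = "".join(aa[parent_states])
            continue
        for child in node.child_nodes():
            t = child.edge.length if child.edge.length is not None else 0.0
            if t == 0.0:
                states[id(child)] = parent_states.copy()
                continue
            P = model.transition_matrix(t)
            child_states = np.empty(length, dtype=np.int64)
            for s in np.unique(parent_states):
                idx = np.nonzero(parent_states == s)[0]
                child_states[idx] = rng.choice(20, size=len(idx), p=P[s])
            states[id(child)] = child_states
    return leaves


def induced_species_tree(
    phylo: PhyloTree, group: str, species_rule=None
) -> dendropy.Tree:
    """The subtree spanned by one paralog group's leaves, relabelled by
    species tag (used to co-simulate a receptor ortholog alignment)."""
    tag = species_tagger(species_rule)
    leaves = [l for l, g in phylo.groups.items() if g == group]
    if not leaves:
        raise ConfigError(f"no leaves in paralog group {group!r}")
    sub = phylo.tree.extract_tree_with_taxa_labels(labels=leaves)
    # re-parse to detach from the source taxon namespace before relabelling
    sub = dendropy.Tree.get(
        data=sub.as_string(schema="newick"),
        schema="newick",
        preserve_underscores=True,
        rooting="default-rooted",
    )
    for lf in sub.leaf_node_iter():
        lf.taxon.label = f"REC_{tag(lf.taxon.label)}"
    return sub


@dataclass
class NullModelConfig:
    """Mirror of the real-data pipeline configuration for the null runs."""

    conservation: ConservationConfig = field(default_factory=ConservationConfig)
    mi: MIConfig = field(default_factory=MIConfig)
    sequence_length: int = 53
    receptor_length: int = 100
    reference_group: str | None = None
    receptor_alignment: Alignment | None = None  # reuse a real receptor instead
    species_rule: object = None


@dataclass
class BackgroundDistribution:
    """Pooled neutral partial scores and their per-component normal fit."""

    mean: dict[str, float]
    sd: dict[str, float]
    samples: dict[str, np.ndarray]
    n_reps: int
    seed: int
    sequence_length: int

    def p_value(self, component: str, score) -> np.ndarray | float:
        """One-sided (upper-tail) normal p-value P(X >= score)."""
        return p_value(score, self.mean[component], self.sd[component])

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": list(COMPONENTS),
                "mean": [self.mean[c] for c in COMPONENTS],
                "sd": [self.sd[c] for c in COMPONENTS],
                "n": [len(self.samples[c]) for c in COMPONENTS],
                "n_reps": self.n_reps,
                "seed": self.seed,
            }
        )


def p_value(score, mu: float, sigma: float):
    """Upper-tail normal probability P(X >= score); a degenerate
    background (sigma == 0) gives 0 above the mean and 1 otherwise."""
    score = np.asarray(score, dtype=float)
    if sigma == 0.0:
        out = np.where(score > mu, 0.0, 1.0)
    else:
        out = stats.norm.sf(score, loc=mu, scale=sigma)
    return float(out) if out.ndim == 0 else out


def _replicate_components(
    phylo: PhyloTree,
    model: SubstitutionModel,
    config: NullModelConfig,
    rng: np.random.Generator,
    species_tree: dendropy.Tree,
):
    """Simulate one neutral family + receptor and score components I-IV."""
    group_leaves = phylo.group_leaves()
    degenerate = [g for g, ls in group_leaves.items() if len(ls) < 2]
    if degenerate:
        import warnings

        warnings.warn(
            f"paralog groups with fewer than two leaves: {degenerate}; "
            "their ortholog conservation is degenerate",
            stacklevel=3,
        )
    leaf_seqs = simulate_evolution(phylo, model, config.sequence_length, rng)
    representatives = {g: ls[0] for g, ls in group_leaves.items()}
    ref_group = config.reference_group or next(iter(group_leaves))
    if ref_group not in group_leaves:
        raise ConfigError(f"reference group {ref_group!r} not in the leaf partition")
    master = Alignment(
        [representatives[g] for g in group_leaves],
        [leaf_seqs[representatives[g]] for g in group_leaves],
    )
    orth_msas = {
        g: Alignment(ls, [leaf_seqs[l] for l in ls]) for g, ls in group_leaves.items()
    }
    ref_ids = dict(representatives)
    if config.receptor_alignment is not None:
        receptor = config.receptor_alignment
    else:
        rec_seqs = simulate_evolution(
            species_tree, model, config.receptor_length, rng
        )
        ids = sorted(rec_seqs)
        receptor = Alignment(ids, [rec_seqs[i] for i in ids])
    return compute_components(
        master=master,
        orth_msas=orth_msas,
        ref_ids=ref_ids,
        ref_paralog=ref_group,
        receptor=receptor,
        cons_cfg=config.conservation,
        mi_cfg=config.mi,
        species_rule=config.species_rule,
    )


def neutral_component_samples(
    phylo: PhyloTree,
    model: SubstitutionModel,
    config: NullModelConfig | None = None,
    n_reps: int = 100,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Per-site partial scores of ``n_reps`` fresh neutral replicates,
    pooled per component (arrays of length n_reps * sequence_length)."""
    config = config or NullModelConfig()
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    ref_group = config.reference_group or next(iter(phylo.group_leaves()))
    species_tree = induced_species_tree(phylo, ref_group, config.species_rule)
    pools: dict[str, list[np.ndarray]] = {c: [] for c in COMPONENTS}
    for r in range(n_reps):
        rng = np.random.default_rng([seed, r])
        comp = _replicate_components(phylo, model, config, rng, species_tree)
        pools["I"].append(comp.I)
        pools["II"].append(comp.II_msa)
        pools["III"].append(comp.III)
        pools["IV"].append(comp.IV)
    return {c: np.concatenate(v) for c, v in pools.items()}


def build_background(
    phylo: PhyloTree,
    model: SubstitutionModel,
    config: NullModelConfig | None = None,
    n_reps: int = 100,
    seed: int = 0,
) -> BackgroundDistribution:
    """Simulate ``n_reps`` neutral replicates and fit one normal per
    component by the method of moments."""
    config = config or NullModelConfig()
    if n_reps < 2:
        raise ConfigError("n_reps must be >= 2 to estimate a spread")
    samples = neutral_component_samples(phylo, model, config, n_reps, seed)
    mean = {c: float(np.mean(v)) for c, v in samples.items()}
    sd = {c: float(np.std(v, ddof=1)) for c, v in samples.items()}
    return BackgroundDistribution(
        mean=mean,
        sd=sd,
        samples=samples,
        n_reps=n_reps,
        seed=seed,
        sequence_length=config.sequence_length,
    )
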