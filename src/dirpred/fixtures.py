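"""Deterministic synthetic input bundles with planted signal.

The generator emulates a paralogous ligand family (default: seven
paralogs, mirroring an EGF-like family) shared by one receptor across a
panel of species.  Sequences descend from a family ancestor through a
uniform substitution kernel: each position mutates with probability
``between_divergence`` on the branch to a paralog ancestor and with
probability ``within_rate`` on the branch to each species.  Planted
sites override this background:

``DIR``
    near-invariant within every paralog's orthologs — one major residue
    per paralog (distinct across paralogs) with a small minority-species
    pattern (``dir_minor_fraction`` of the species carry one alternative
    residue) — plus a dedicated receptor column whose residue is a fixed
    injective function of the reference ligand's residue in each
    species.  The minority pattern is what makes the receptor
    covariation *detectable*: mutual information of a strictly constant
    column is identically zero, so a planted divergence-inducing site
    must retain a little within-ortholog variation to coevolve visibly
    with the receptor, exactly as real specificity residues do;
``cysteine-like``
    the same residue in every sequence of every paralog (the structural
    cysteine analogue);
``receptor-covarying``
    varies across species with a matching receptor column (maximal
    ligand-receptor mutual information);
``neutral``
    background behaviour, recorded in the manifest only.

The bundle (master alignment, one ortholog alignment per paralog,
receptor alignment, rooted tree with branch lengths, ground-truth
manifest) is valid input for the whole pipeline; the structure-based
paralog alignment is emitted column-identical to the sequence-based one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .alignio import AMINO_ACIDS, Alignment, write_alignment
from .exceptions import ConfigError

MODES = ("DIR", "cysteine-like", "neutral", "receptor-covarying")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic ligand-family system."""

    n_paralogs: int = 7
    n_species: int = 12
    ligand_length: int = 60
    receptor_length: int = 120
    planted_sites: tuple[tuple[int, str], ...] = ((30, "DIR"),)
    within_rate: float = 0.4
    between_divergence: float = 0.15
    dir_minor_fraction: float = 1 / 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.within_rate <= 1.0:
            raise ConfigError("within_rate must be in [0, 1]")
        if not 0.0 <= self.dir_minor_fraction < 0.5:
            raise ConfigError("dir_minor_fraction must be in [0, 0.5)")
        if not 0.0 <= self.between_divergence <= 1.0:
            raise ConfigError("between_divergence must be in [0, 1]")
        for pos, mode in self.planted_sites:
            if mode not in MODES:
                raise ConfigError(f"unknown planted-site mode {mode!r}")
            if not 1 <= pos <= self.ligand_length:
                raise ConfigError(
                    f"planted site {pos} outside 1..{self.ligand_length}"
                )
        if len({p for p, _ in self.planted_sites}) != len(self.planted_sites):
            raise ConfigError("planted sites must be at distinct positions")


@dataclass
class SyntheticSystem:
    """A complete input bundle plus its ground-truth manifest."""

    master: Alignment
    msta: Alignment
    ortholog_msas: dict[str, Alignment]
    receptor: Alignment
    tree_newick: str
    ref_paralog: str
    ref_id: str
    manifest: dict = field(default_factory=dict)

    @property
    def ref_ids(self) -> dict[str, str]:
        return {p: aln.ids[0] for p, aln in self.ortholog_msas.items()}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the bundle as FASTA/newick/JSON files; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for name, aln in [("master", self.master), ("msta", self.msta)]:
            paths[name] = outdir / f"{name}.fasta"
            write_alignment(aln, paths[name])
        for paralog, aln in self.ortholog_msas.items():
            key = f"orthologs_{paralog}"
            paths[key] = outdir / f"{key}.fasta"
            write_alignment(aln, paths[key])
        paths["receptor"] = outdir / "receptor.fasta"
        write_alignment(self.receptor, paths["receptor"])
        paths["tree"] = outdir / "tree.nwk"
        paths["tree"].write_text(self.tree_newick + "\n")
        paths["manifest"] = outdir / "manifest.json"
        paths["manifest"].write_text(json.dumps(self.manifest, indent=2) + "\n")
        return paths


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform substitution kernel: each position mutates with
    probability ``rate`` to one of the 19 other residues."""
    out = seq.copy()
    hit = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hit):
        shift = rng.integers(1, 20, size=len(hit))
        out[hit] = (out[hit] + shift) % 20
    return out


def make_synthetic_system(spec: FixtureSpec) -> SyntheticSystem:
    """Generate one deterministic synthetic system from its spec."""
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AMINO_ACIDS))
    paralogs = [f"L{k + 1}" for k in range(spec.n_paralogs)]
    species = [f"sp{k + 1:02d}" for k in range(spec.n_species)]
    L, R = spec.ligand_length, spec.receptor_length

    ancestor = rng.integers(0, 20, size=L)
    paralog_anc = {p: _mutate(ancestor, spec.between_divergence, rng) for p in paralogs}
    # the reference species carries each paralog's representative
    # (ancestral) sequence — master rows are curated representatives,
    # not noisy extant sequences
    ligand = {
        p: {
            s: (
                paralog_anc[p].copy()
                if s == species[0]
                else _mutate(paralog_anc[p], spec.within_rate, rng)
            )
            for s in species
        }
        for p in paralogs
    }
    receptor_anc = rng.integers(0, 20, size=R)
    receptor = {
        s: (
            receptor_anc.copy()
            if s == species[0]
            else _mutate(receptor_anc, spec.within_rate, rng)
        )
        for s in species
    }

    cys_code = AMINO_ACIDS.index("C")
    receptor_cols: dict[int, int] = {}
    free_rec_cols = list(rng.permutation(R))
    planted_manifest = []
    for pos, mode in spec.planted_sites:
        j = pos - 1
        entry = {"position": pos, "mode": mode}
        if mode == "neutral":
            planted_manifest.append(entry)
            continue
        if mode == "cysteine-like":
            for p in paralogs:
                for s in species:
                    ligand[p][s][j] = cys_code
        elif mode == "DIR":
            # one major + one minor residue per paralog, all distinct
            picks = rng.choice(20, size=2 * spec.n_paralogs, replace=False)
            major, minor = picks[: spec.n_paralogs], picks[spec.n_paralogs :]
            n_minor = max(1, round(spec.dir_minor_fraction * spec.n_species))
            # the reference species (index 0) always carries the major
            # residue: the representative sequence defines the site
            minor_species = set(
                (1 + rng.choice(spec.n_species - 1, size=n_minor, replace=False)).tolist()
            )
            # injective residue->residue map for the covarying receptor column
            codomain = rng.permutation(20)
            rec_col = int(free_rec_cols.pop())
            receptor_cols[pos] = rec_col
            for k, p in enumerate(paralogs):
                for si, s in enumerate(species):
                    ligand[p][s][j] = minor[k] if si in minor_species else major[k]
            for si, s in enumerate(species):
                ref_res = int(minor[0] if si in minor_species else major[0])
                receptor[s][rec_col] = codomain[ref_res]
            entry["receptor_column"] = rec_col
            entry["residues"] = {p: str(aa[major[k]]) for k, p in enumerate(paralogs)}
            entry["minor_species"] = sorted(species[si] for si in minor_species)
        elif mode == "receptor-covarying":
            # species-indexed pattern over four residues, mirrored in the
            # receptor through an injective relabelling
            pattern = rng.choice(20, size=4, replace=False)
            codomain = rng.permutation(20)
            rec_col = int(free_rec_cols.pop())
            receptor_cols[pos] = rec_col
            for si, s in enumerate(species):
                res = int(pattern[si % 4])
                for p in paralogs:
                    ligand[p][s][j] = res
                receptor[s][rec_col] = codomain[res]
            entry["receptor_column"] = rec_col
        planted_manifest.append(entry)

    def to_str(codes: np.ndarray) -> str:
        return "".join(aa[codes])

    orth_msas = {
        p: Alignment(
            [f"{p}_{s}" for s in species], [to_str(ligand[p][s]) for s in species]
        )
        for p in paralogs
    }
    ref_species = species[0]
    master = Alignment(
        [f"{p}_{ref_species}" for p in paralogs],
        [to_str(ligand[p][ref_species]) for p in paralogs],
    )
    msta = Alignment(list(master.ids), list(master.seqs))
    receptor_aln = Alignment(
        [f"REC_{s}" for s in species], [to_str(receptor[s]) for s in species]
    )

    # Poisson-corrected branch lengths: a per-site substitution
    # probability p corresponds to -ln(1 - p) expected substitutions.
    # The reference species carries the representative sequence, hence a
    # zero-length terminal branch.
    within_branch = -np.log(max(1.0 - spec.within_rate, 1e-9))
    between_branch = -np.log(max(1.0 - spec.between_divergence, 1e-9))
    clades = []
    for p in paralogs:
        tips = ",".join(
            f"{p}_{s}:{0.0 if s == species[0] else within_branch:.6g}"
            for s in species
        )
        clades.append(f"({tips}):{between_branch:.6g}")
    tree_newick = "(" + ",".join(clades) + ");"

    manifest = {
        "spec": asdict(spec),
        "ref_paralog": paralogs[0],
        "ref_id": f"{paralogs[0]}_{ref_species}",
        "planted_sites": planted_manifest,
        "receptor_columns": {str(k): v for k, v in receptor_cols.items()},
        "paralogs": paralogs,
        "species": species,
    }
    return SyntheticSystem(
        master=master,
        msta=msta,
        ortholog_msas=orth_msas,
        receptor=receptor_aln,
        tree_newick=tree_newick,
        ref_paralog=paralogs[0],
        ref_id=f"{paralogs[0]}_{ref_species}",
        manifest=manifest,
    )
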