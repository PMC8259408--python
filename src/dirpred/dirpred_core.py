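"""Assembly of the four per-site partial scores and the combined ranking.

For every residue position of the reference ligand (1-based over its
ungapped sequence) four scores on [0, 1] are combined:

  I   ortholog conservation, averaged over the reference ligand and every
      other paralog alignable at that site;
  II  1 - conservation in the paralog master alignment (sequence-based
      MSA and, optionally, structure-based MSTA);
  III strongest mutual-information coupling with any receptor site;
  IV  1 - strongest mutual-information coupling with any other ligand
      site in the joint ortholog alignment.

The combined score is the weighted sum (default unit weights, so totals
live on [0, 4]); sites are ranked in descending total with ties broken by
ascending reference position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from typing import Mapping

from .alignio import (
    Alignment,
    ReferenceMap,
    build_reference_map,
    pair_by_species,
    project_orthologs_onto_master,
)
from .conservation import ConservationConfig, ConservationProfile, conservation_profile
from .coevolution import (
    MIConfig,
    ligand_internal_component,
    ligand_receptor_component,
)
from .exceptions import ConfigError


def ortholog_component(
    ref_profile: ConservationProfile,
    ref_map: ReferenceMap,
    other_profiles: dict[str, ConservationProfile],
    master_map: ReferenceMap,
) -> np.ndarray:
    """Component I: mean ortholog conservation across the family.

    ``ref_profile`` is scored on the reference ligand's own ortholog
    alignment (indexed through ``ref_map``); each entry of
    ``other_profiles`` is scored on another paralog's ortholog block
    already projected onto master columns (indexed through
    ``master_map``).  Paralogs whose block is flagged (gapped) at a site
    are skipped, shrinking the divisor; if every other paralog is
    skipped the reference's own conservation stands alone.
    """
    n_sites = master_map.n_sites
    if ref_map.n_sites != n_sites:
        raise ConfigError(
            "reference maps of the ortholog and master alignments disagree "
            f"({ref_map.n_sites} vs {n_sites} sites)"
        )
    out = np.zeros(n_sites)
    for i in range(n_sites):
        vals = [ref_profile.scores[ref_map.column_of(i + 1)]]
        c = master_map.column_of(i + 1)
        for prof in other_profiles.values():
            if not prof.flagged[c]:
                vals.append(prof.scores[c])
        out[i] = float(np.mean(vals))
    return out


def paralog_component(
    master_profile: ConservationProfile, master_map: ReferenceMap
) -> tuple[np.ndarray, np.ndarray]:
    """Component II: per site, (paralog conservation x, 1 - x)."""
    cols = master_map.columns
    x = master_profile.scores[cols]
    return x, 1.0 - x


@dataclass
class ComponentScores:
    """Per-reference-site partial scores (all on [0, 1])."""

    ref_position: np.ndarray  # 1-based
    ref_residue: list[str]
    I: np.ndarray
    II_msa: np.ndarray
    III: np.ndarray
    IV: np.ndarray
    x_paralog_msa: np.ndarray
    II_msta: np.ndarray | None = None
    x_paralog_msta: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return len(self.ref_position)

    @property
    def has_msta(self) -> bool:
        return self.II_msta is not None


@dataclass
class DIRpredResult:
    """Combined per-site scores, ranks and (optionally) p-values."""

    components: ComponentScores
    weights: np.ndarray
    total_msa: np.ndarray
    rank_msa: np.ndarray
    total_msta: np.ndarray | None = None
    rank_msta: np.ndarray | None = None
    p_values: dict[str, np.ndarray] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """The single per-site output table."""
        c = self.components
        nan = np.full(c.n_sites, np.nan)
        df = pd.DataFrame(
            {
                "ref_position": c.ref_position,
                "ref_residue": c.ref_residue,
                "I": c.I,
                "x_paralog_msa": c.x_paralog_msa,
                "II_msa": c.II_msa,
                "x_paralog_msta": (
                    c.x_paralog_msta if c.has_msta else nan
                ),
                "II_msta": c.II_msta if c.has_msta else nan,
                "III": c.III,
                "IV": c.IV,
                "total_msa": self.total_msa,
                "total_msta": self.total_msta if self.total_msta is not None else nan,
                "rank_msa": self.rank_msa,
                "rank_msta": (
                    self.rank_msta
                    if self.rank_msta is not None
                    else np.full(c.n_sites, -1)
                ),
                "p_I": self.p_values.get("I", nan),
                "p_II": self.p_values.get("II", nan),
                "p_III": self.p_values.get("III", nan),
                "p_IV": self.p_values.get("IV", nan),
            }
        )
        return df


def combine(components: ComponentScores, weights=(1.0, 1.0, 1.0, 1.0)) -> DIRpredResult:
    """Weighted sum of the four components, for the MSA-based paralog
    score and, when present, the MSTA-based one."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (4,):
        raise ConfigError("weights must be a 4-vector")
    if (w < 0).any():
        raise ConfigError("weights must be non-negative")
    if not (w > 0).any():
        raise ConfigError("weights must not all be zero")
    c = components
    total_msa = w[0] * c.I + w[1] * c.II_msa + w[2] * c.III + w[3] * c.IV
    result = DIRpredResult(
        components=c,
        weights=w,
        total_msa=total_msa,
        rank_msa=_rank(total_msa, c.ref_position),
    )
    if c.has_msta:
        result.total_msta = w[0] * c.I + w[1] * c.II_msta + w[2] * c.III + w[3] * c.IV
        result.rank_msta = _rank(result.total_msta, c.ref_position)
    return result


def _rank(totals: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Rank 1 = highest total; ties broken by ascending position."""
    order = np.lexsort((positions, -totals))
    ranks = np.empty(len(totals), dtype=int)
    ranks[order] = np.arange(1, len(totals) + 1)
    return ranks


def rank_sites(result: DIRpredResult) -> DIRpredResult:
    """Recompute ranks in place (idempotent) and return the result."""
    c = result.components
    result.rank_msa = _rank(result.total_msa, c.ref_position)
    if result.total_msta is not None:
        result.rank_msta = _rank(result.total_msta, c.ref_position)
    return result


def compute_components(
    master: Alignment,
    orth_msas: Mapping[str, Alignment],
    ref_ids: Mapping[str, str],
    ref_paralog: str,
    receptor: Alignment,
    cons_cfg: ConservationConfig | None = None,
    mi_cfg: MIConfig | None = None,
    msta: Alignment | None = None,
    species_rule=None,
) -> ComponentScores:
    """Run the full component stage on one input bundle.

    ``orth_msas`` maps each paralog name to its ortholog alignment and
    ``ref_ids`` to the identifier of that paralog's reference row (which
    must also be its row identifier in the master alignment).
    ``ref_paralog`` selects the reference ligand.  ``msta`` is the
    optional structure-superposition paralog alignment; when given it
    must contain the same reference row and yields the second paralog
    component.
    """
    cons_cfg = cons_cfg or ConservationConfig()
    mi_cfg = mi_cfg or MIConfig()
    if ref_paralog not in orth_msas:
        raise ConfigError(f"reference paralog {ref_paralog!r} has no ortholog alignment")
    if receptor is None:
        raise ConfigError("a receptor ortholog alignment is required (component III)")
    ref_id = ref_ids[ref_paralog]
    master_map = build_reference_map(master, ref_id)

    projection = project_orthologs_onto_master(master, orth_msas, ref_ids)
    ref_orth = orth_msas[ref_paralog]
    ref_orth_map = build_reference_map(ref_orth, ref_id)
    ref_profile = conservation_profile(ref_orth, cons_cfg, ref_row=ref_id)
    other_profiles = {
        p: conservation_profile(projection.blocks[p], cons_cfg, ref_row=ref_ids[p])
        for p in orth_msas
        if p != ref_paralog
    }
    I = ortholog_component(ref_profile, ref_orth_map, other_profiles, master_map)

    master_profile = conservation_profile(master, cons_cfg, ref_row=ref_id)
    x_msa, II_msa = paralog_component(master_profile, master_map)
    x_msta = II_msta = None
    if msta is not None:
        msta_map = build_reference_map(msta, ref_id)
        if msta_map.residues != master_map.residues:
            raise ConfigError(
                "MSA and MSTA disagree on the reference ligand's sequence"
            )
        msta_profile = conservation_profile(msta, cons_cfg, ref_row=ref_id)
        x_msta, II_msta = paralog_component(msta_profile, msta_map)

    paired = pair_by_species(ref_orth, receptor, species_rule)
    # the ligand block keeps the ortholog alignment's columns, so the
    # ortholog reference map applies unchanged
    III, _, _ = ligand_receptor_component(paired, ref_orth_map, mi_cfg)
    IV, _, _ = ligand_internal_component(projection.joint(), master_map, mi_cfg)

    return ComponentScores(
        ref_position=np.arange(1, master_map.n_sites + 1),
        ref_residue=list(master_map.residues),
        I=I,
        II_msa=II_msa,
        III=III,
        IV=IV,
        x_paralog_msa=x_msa,
        II_msta=II_msta,
        x_paralog_msta=x_msta,
    )


def cross_tables(components: ComponentScores) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The two per-site cross-score tables.

    Table 1 crosses ortholog conservation (I) with paralog conservation
    (x = 1 - II); table 2 crosses ligand-receptor coevolution (III) with
    ligand-ligand coevolution (1 - IV).
    """
    c = components
    conservation = pd.DataFrame(
        {
            "ref_position": c.ref_position,
            "ref_residue": c.ref_residue,
            "ortholog_conservation": c.I,
            "paralog_conservation_msa": c.x_paralog_msa,
        }
    )
    if c.has_msta:
        conservation["paralog_conservation_msta"] = c.x_paralog_msta
    coevolution = pd.DataFrame(
        {
            "ref_position": c.ref_position,
            "ref_residue": c.ref_residue,
            "ligand_receptor_coevolution": c.III,
            "ligand_ligand_coevolution": 1.0 - c.IV,
        }
    )
    return conservation, coevolution
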