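"""Mutual-information coevolution between alignment columns.

MI is the plug-in estimator sum p(a,b) log2[p(a,b) / (p(a) p(b))] over the
rows where neither column is gapped (pairwise deletion).  By default MI is
normalized by the joint entropy H(A,B), which bounds it to [0, 1] and makes
it commensurate with the conservation components.  Pairs with fewer than
``min_pairs`` gap-free rows are masked — distinguishable from a true 0.

Two site-level summaries feed the combined score: the ligand-receptor
component (max normalized MI between a ligand site and any receptor column,
computed across species-paired ortholog alignments) and the complement of
the strongest intra-ligand coupling in the joint ortholog alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .alignio import GAP_CODE, Alignment, PairedAlignment, ReferenceMap
from .exceptions import ConfigError

NORMALIZATIONS = ("joint-entropy", "min-entropy", "none")


@dataclass
class MIConfig:
    normalization: str = "joint-entropy"
    min_pairs: int = 5
    apc: bool = False  # average-product correction on full matrices

    def __post_init__(self) -> None:
        if self.normalization not in NORMALIZATIONS:
            raise ConfigError(f"unknown MI normalization {self.normalization!r}")
        if self.min_pairs < 2:
            raise ConfigError("min_pairs must be >= 2")


def _entropies(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Marginal and joint entropies (bits) of two gap-free code vectors."""
    n = len(a)
    joint = np.bincount(a.astype(np.int64) * 20 + b, minlength=400).astype(float)
    joint = joint[joint > 0]
    ca = np.bincount(a, minlength=20).astype(float)
    cb = np.bincount(b, minlength=20).astype(float)
    log2n = np.log2(n)

    def _h(counts: np.ndarray) -> float:
        return float(log2n - xlogy(counts, counts).sum() / (n * np.log(2.0)))

    return _h(ca[ca > 0]), _h(cb[cb > 0]), _h(joint)


def column_mi(
    col_a: np.ndarray, col_b: np.ndarray, cfg: MIConfig | None = None
) -> float | None:
    """Plug-in MI in bits between two coded columns, or ``None`` when
    fewer than ``min_pairs`` gap-free row pairs remain."""
    cfg = cfg or MIConfig()
    ok = (col_a != GAP_CODE) & (col_b != GAP_CODE)
    if int(ok.sum()) < cfg.min_pairs:
        return None
    ha, hb, hab = _entropies(col_a[ok], col_b[ok])
    return max(ha + hb - hab, 0.0)


def normalized_mi(
    col_a: np.ndarray, col_b: np.ndarray, cfg: MIConfig | None = None
) -> float | None:
    """MI normalized to [0, 1]; ``None`` when masked by ``min_pairs``."""
    cfg = cfg or MIConfig()
    ok = (col_a != GAP_CODE) & (col_b != GAP_CODE)
    if int(ok.sum()) < cfg.min_pairs:
        return None
    ha, hb, hab = _entropies(col_a[ok], col_b[ok])
    mi = max(ha + hb - hab, 0.0)
    if cfg.normalization == "none":
        return mi
    denom = hab if cfg.normalization == "joint-entropy" else min(ha, hb)
    if denom <= 0.0:
        return 0.0
    return float(min(mi / denom, 1.0))


@dataclass
class MIMatrix:
    """Symmetric normalized-MI matrix with a validity mask."""

    values: np.ndarray  # (n, n); masked entries hold 0
    mask: np.ndarray  # bool (n, n); True where invalidated by min_pairs


def mi_matrix(aln: Alignment, cfg: MIConfig | None = None) -> MIMatrix:
    """Full column-by-column normalized-MI matrix of one alignment.

    The diagonal is the self normalized MI (1 for non-constant columns,
    0 for constant ones).  With ``cfg.apc`` the average-product
    correction is subtracted from off-diagonal entries (clipped at 0).
    """
    cfg = cfg or MIConfig()
    codes = aln.codes()
    n = aln.n_cols
    values = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i, n):
            v = normalized_mi(codes[:, i], codes[:, j], cfg)
            if v is None:
                mask[i, j] = mask[j, i] = True
            else:
                values[i, j] = values[j, i] = v
    if cfg.apc:
        off = ~np.eye(n, dtype=bool) & ~mask
        if off.any():
            vals = np.where(off, values, 0.0)
            counts = off.sum(axis=1)
            row_mean = np.divide(
                vals.sum(axis=1), counts, out=np.zeros(n), where=counts > 0
            )
            total = vals.sum() / max(off.sum(), 1)
            if total > 0:
                corr = np.outer(row_mean, row_mean) / total
                values = np.where(off, np.clip(values - corr, 0.0, None), values)
    return MIMatrix(values, mask)


def ligand_receptor_component(
    paired: PairedAlignment, ligand_map: ReferenceMap, cfg: MIConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Component III: per reference ligand site, the max normalized MI
    against every receptor column.

    Returns ``(scores, argmax_receptor_column, flagged)``; a site whose
    every receptor pairing is masked scores 0 and is flagged (its argmax
    is -1).  Ties in the max go to the lowest receptor column index.
    """
    cfg = cfg or MIConfig()
    if paired.receptor_block.n_cols == 0:
        raise ConfigError("receptor block has no columns")
    lig_codes = paired.ligand_block.codes()
    rec_codes = paired.receptor_block.codes()
    n_sites = ligand_map.n_sites
    scores = np.zeros(n_sites)
    argmax = np.full(n_sites, -1, dtype=int)
    flagged = np.zeros(n_sites, dtype=bool)
    for i in range(n_sites):
        col = lig_codes[:, ligand_map.column_of(i + 1)]
        best, best_j = -1.0, -1
        for j in range(rec_codes.shape[1]):
            v = normalized_mi(col, rec_codes[:, j], cfg)
            if v is not None and v > best:
                best, best_j = v, j
        if best_j < 0:
            flagged[i] = True
        else:
            scores[i], argmax[i] = best, best_j
    return scores, argmax, flagged


def ligand_internal_component(
    joint: Alignment, master_map: ReferenceMap, cfg: MIConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Component IV: per reference site, 1 minus the max normalized MI
    against every *other* master column of the joint ortholog alignment.

    Returns ``(scores, argmax_column, flagged)``; a site with every
    pairing masked scores 1 (no detectable internal coupling) and is
    flagged.
    """
    cfg = cfg or MIConfig()
    if joint.n_cols < 2:
        raise ConfigError("joint alignment must have at least two columns")
    codes = joint.codes()
    n_sites = master_map.n_sites
    scores = np.ones(n_sites)
    argmax = np.full(n_sites, -1, dtype=int)
    flagged = np.zeros(n_sites, dtype=bool)
    for i in range(n_sites):
        ci = master_map.column_of(i + 1)
        col = codes[:, ci]
        best, best_j = -1.0, -1
        for j in range(joint.n_cols):
            if j == ci:
                continue
            v = normalized_mi(col, codes[:, j], cfg)
            if v is not None and v > best:
                best, best_j = v, j
        if best_j < 0:
            flagged[i] = True
        else:
            scores[i], argmax[i] = 1.0 - best, best_j
    return scores, argmax, flagged
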