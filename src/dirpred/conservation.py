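"""Per-column conservation scores in three formulations.

All three scores live on [0, 1] so they can be combined and complemented
commensurately downstream:

``identity``
    Frequency of the reference residue in the column, counting gaps in
    the denominator (an indel against the reference is evidence of
    non-conservation).

``blosum``
    Mean min-max-normalized BLOSUM62 similarity between the reference
    residue and each non-gap residue of the column, using the global
    extremes of the 20x20 matrix.

``jsdw``
    Window-smoothed Jensen-Shannon divergence between the column's
    empirical residue distribution and a background distribution
    (Capra-Singh style): the per-column JSD is scaled to [0, 1] by its
    lambda-dependent maximum, multiplied by the column's non-gap
    fraction as a gap penalty, and linearly mixed with the mean score of
    the flanking window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.special import rel_entr

from .alignio import AMINO_ACIDS, GAP, GAP_CODE, Alignment, encode
from .exceptions import AlphabetError, ConfigError

METHODS = ("identity", "blosum", "jsdw")


def load_blosum62() -> np.ndarray:
    """The packaged BLOSUM62 matrix as a 20x20 float array in canonical
    (alphabetical) residue order."""
    text = resources.files("dirpred.data").joinpath("blosum62.txt").read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split()
    rows = {ln.split()[0]: [int(v) for v in ln.split()[1:]] for ln in lines[1:]}
    mat = np.empty((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            mat[i, j] = rows[a][header.index(b)]
    return mat


def load_background() -> np.ndarray:
    """BLOSUM62-derived background amino-acid frequencies (canonical
    order), renormalized to sum exactly to 1."""
    text = resources.files("dirpred.data").joinpath("blosum62_freqs.txt").read_text()
    freqs = {}
    for ln in text.splitlines():
        if ln.strip() and not ln.startswith("#"):
            aa, v = ln.split()
            freqs[aa] = float(v)
    vec = np.array([freqs[a] for a in AMINO_ACIDS])
    return vec / vec.sum()


@dataclass
class ConservationConfig:
    """Configuration shared by the three conservation formulations.

    window_size / window_weight / jsd_lambda follow the defaults of the
    Capra-Singh JSD conservation method (window of 3 on each side,
    half weight to the window mean, balanced lambda).
    """

    method: str = "identity"
    matrix: np.ndarray = field(default_factory=load_blosum62)
    background: np.ndarray = field(default_factory=load_background)
    window_size: int = 3
    window_weight: float = 0.5
    jsd_lambda: float = 0.5

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(f"unknown conservation method {self.method!r}")
        if self.window_size < 0:
            raise ConfigError("window_size must be >= 0")
        if not 0.0 <= self.window_weight <= 1.0:
            raise ConfigError("window_weight must be in [0, 1]")
        if not 0.0 <= self.jsd_lambda <= 1.0:
            raise ConfigError("jsd_lambda must be in [0, 1]")
        if abs(float(np.sum(self.background)) - 1.0) > 1e-12:
            raise ConfigError("background frequencies must sum to 1")


def _as_codes(column: Sequence[str] | np.ndarray) -> np.ndarray:
    if isinstance(column, np.ndarray) and column.dtype == np.int8:
        return column
    return encode("".join(column))


def identity_score(column: Sequence[str] | np.ndarray, ref_residue: str) -> float:
    """Frequency of ``ref_residue`` in the column; gaps count in the
    denominator.  An all-gap column scores 0."""
    codes = _as_codes(column)
    if ref_residue not in AMINO_ACIDS:
        raise AlphabetError(f"reference residue {ref_residue!r} is not canonical")
    ref_code = AMINO_ACIDS.index(ref_residue)
    return float(np.count_nonzero(codes == ref_code)) / len(codes)


def blosum_score(
    column: Sequence[str] | np.ndarray, ref_residue: str, matrix: np.ndarray
) -> float:
    """Mean min-max-normalized substitution score of the reference
    residue against the column's non-gap residues; all-gap column -> 0."""
    codes = _as_codes(column)
    if ref_residue not in AMINO_ACIDS:
        raise AlphabetError(f"reference residue {ref_residue!r} is not canonical")
    ref_code = AMINO_ACIDS.index(ref_residue)
    residues = codes[codes != GAP_CODE]
    if len(residues) == 0:
        return 0.0
    s_min, s_max = matrix.min(), matrix.max()
    return float(np.mean((matrix[ref_code, residues] - s_min) / (s_max - s_min)))


def _column_distribution(codes: np.ndarray) -> tuple[np.ndarray, float]:
    """Empirical residue distribution over non-gap rows and the non-gap
    fraction.  No pseudocounts; the JSD mixture guards log(0)."""
    counts = np.bincount(codes[codes != GAP_CODE], minlength=20).astype(float)
    n = counts.sum()
    if n == 0:
        return counts, 0.0
    return counts / n, n / len(codes)


def jsd_score(
    column: Sequence[str] | np.ndarray,
    background: np.ndarray,
    jsd_lambda: float = 0.5,
) -> float:
    """Jensen-Shannon divergence (log base 2) between the column's
    residue distribution and the background, scaled to [0, 1] by the
    lambda-dependent maximum and multiplied by the non-gap fraction."""
    codes = _as_codes(column)
    p, nongap = _column_distribution(codes)
    if nongap == 0.0:
        return 0.0
    lam = jsd_lambda
    r = lam * p + (1.0 - lam) * background
    with np.errstate(divide="ignore", invalid="ignore"):
        jsd = lam * rel_entr(p, r).sum() + (1.0 - lam) * rel_entr(background, r).sum()
    jsd /= np.log(2.0)
    if lam in (0.0, 1.0):
        return 0.0  # the divergence degenerates to KL(x||x) = 0
    max_jsd = -(lam * np.log2(lam) + (1.0 - lam) * np.log2(1.0 - lam))
    return float(np.clip(jsd / max_jsd, 0.0, 1.0)) * nongap


def jsd_window_score(
    profile: np.ndarray, col: int, window_size: int = 3, window_weight: float = 0.5
) -> float:
    """Mix a column's base JSD with the mean base JSD of the up-to-
    ``window_size`` columns on each side (center excluded, window
    truncated at the edges)."""
    if window_size < 0:
        raise ConfigError("window_size must be >= 0")
    if window_size == 0 or window_weight == 0.0:
        return float(profile[col])
    lo = max(0, col - window_size)
    hi = min(len(profile), col + window_size + 1)
    neighbors = np.concatenate([profile[lo:col], profile[col + 1 : hi]])
    if len(neighbors) == 0:
        return float(profile[col])
    return float(
        (1.0 - window_weight) * profile[col] + window_weight * neighbors.mean()
    )


@dataclass
class ConservationProfile:
    """Per-column conservation with bookkeeping.

    ``flagged`` marks columns that score 0 by fiat: columns where the
    reference row is gapped (when a reference row is given) and all-gap
    columns.
    """

    scores: np.ndarray
    method: str
    gap_fraction: np.ndarray
    flagged: np.ndarray  # bool per column

    def __len__(self) -> int:
        return len(self.scores)


def conservation_profile(
    aln: Alignment, cfg: ConservationConfig, ref_row: str | None = None
) -> ConservationProfile:
    """Score every column of ``aln`` with the configured method.

    ``identity`` and ``blosum`` require ``ref_row``; its residue at each
    column is the reference residue.  Columns where the reference row is
    gapped score 0 and are flagged.  For ``jsdw`` the base JSD profile is
    computed on all columns first (so the window sees real neighbors) and
    reference-gapped columns are zeroed afterwards.
    """
    codes = aln.codes()
    n_cols = aln.n_cols
    gap_fraction = np.count_nonzero(codes == GAP_CODE, axis=0) / aln.n_rows
    if cfg.method in ("identity", "blosum"):
        if ref_row is None:
            raise ConfigError(f"method {cfg.method!r} requires a reference row")
        ref = aln.row(ref_row)
        scores = np.zeros(n_cols)
        flagged = np.zeros(n_cols, dtype=bool)
        for j in range(n_cols):
            if ref[j] == GAP or gap_fraction[j] == 1.0:
                flagged[j] = True
                continue
            if cfg.method == "identity":
                scores[j] = identity_score(codes[:, j], ref[j])
            else:
                scores[j] = blosum_score(codes[:, j], ref[j], cfg.matrix)
        return ConservationProfile(scores, cfg.method, gap_fraction, flagged)

    base = np.array(
        [jsd_score(codes[:, j], cfg.background, cfg.jsd_lambda) for j in range(n_cols)]
    )
    scores = np.array(
        [
            jsd_window_score(base, j, cfg.window_size, cfg.window_weight)
            for j in range(n_cols)
        ]
    )
    flagged = gap_fraction == 1.0
    if ref_row is not None:
        ref = aln.row(ref_row)
        flagged = flagged | np.array([ch == GAP for ch in ref])
    scores[flagged] = 0.0
    return ConservationProfile(scores, cfg.method, gap_fraction, flagged)
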