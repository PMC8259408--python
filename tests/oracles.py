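"""Independent brute-force reference implementations used as oracles.

Everything here is written from the mathematical definitions with plain
loops and dictionaries, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

AA = "ACDEFGHIKLMNPQRSTVWY"


def oracle_identity(column: str, ref: str) -> float:
    return sum(1 for c in column if c == ref) / len(column)


def oracle_blosum(column: str, ref: str, matrix) -> float:
    smin = min(matrix[i][j] for i in range(20) for j in range(20))
    smax = max(matrix[i][j] for i in range(20) for j in range(20))
    vals = [
        (matrix[AA.index(ref)][AA.index(c)] - smin) / (smax - smin)
        for c in column
        if c != "-"
    ]
    return sum(vals) / len(vals) if vals else 0.0


def oracle_jsd(column: str, background, lam: float = 0.5) -> float:
    residues = [c for c in column if c != "-"]
    if not residues:
        return 0.0
    p = [residues.count(a) / len(residues) for a in AA]
    q = list(background)
    r = [lam * pi + (1 - lam) * qi for pi, qi in zip(p, q)]

    def kl(u, v):
        return sum(
            ui * math.log2(ui / vi) for ui, vi in zip(u, v) if ui > 0
        )

    jsd = lam * kl(p, r) + (1 - lam) * kl(q, r)
    max_jsd = -(lam * math.log2(lam) + (1 - lam) * math.log2(1 - lam))
    return min(max(jsd / max_jsd, 0.0), 1.0) * (len(residues) / len(column))


def oracle_jsdw_profile(
    rows: list[str], background, lam=0.5, window=3, weight=0.5
) -> list[float]:
    n = len(rows[0])
    base = [oracle_jsd("".join(r[j] for r in rows), background, lam) for j in range(n)]
    out = []
    for j in range(n):
        neigh = [base[k] for k in range(max(0, j - window), min(n, j + window + 1)) if k != j]
        if window == 0 or not neigh:
            out.append(base[j])
        else:
            out.append((1 - weight) * base[j] + weight * sum(neigh) / len(neigh))
    return out


def oracle_mi(col_a: str, col_b: str) -> float | None:
    """Plug-in MI in bits over gap-free row pairs; None if no pairs."""
    pairs = [(a, b) for a, b in zip(col_a, col_b) if a != "-" and b != "-"]
    if not pairs:
        return None
    n = len(pairs)
    pa: dict[str, int] = {}
    pb: dict[str, int] = {}
    pab: dict[tuple, int] = {}
    for a, b in pairs:
        pa[a] = pa.get(a, 0) + 1
        pb[b] = pb.get(b, 0) + 1
        pab[(a, b)] = pab.get((a, b), 0) + 1
    mi = 0.0
    for (a, b), c in pab.items():
        mi += (c / n) * math.log2((c / n) / ((pa[a] / n) * (pb[b] / n)))
    return max(mi, 0.0)


def oracle_joint_entropy(col_a: str, col_b: str) -> float:
    pairs = [(a, b) for a, b in zip(col_a, col_b) if a != "-" and b != "-"]
    n = len(pairs)
    pab: dict[tuple, int] = {}
    for ab in pairs:
        pab[ab] = pab.get(ab, 0) + 1
    return -sum((c / n) * math.log2(c / n) for c in pab.values())


def oracle_nmi(col_a: str, col_b: str, min_pairs: int = 5) -> float | None:
    pairs = [(a, b) for a, b in zip(col_a, col_b) if a != "-" and b != "-"]
    if len(pairs) < min_pairs:
        return None
    mi = oracle_mi(col_a, col_b)
    h = oracle_joint_entropy(col_a, col_b)
    if h <= 0:
        return 0.0
    return min(mi / h, 1.0)
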