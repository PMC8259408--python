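"""Tabular output and cosmetic plots.

The tab-separated tables are the bit-stable ground truth: header row,
'.' decimal separator, 6 significant digits, rows ordered by reference
position.  Plots are a convenience recap and may fail without failing
the pipeline.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .dirpred_core import DIRpredResult, cross_tables


def format_table(df: pd.DataFrame) -> str:
    """Render a DataFrame as a deterministic TSV string (6 significant
    digits, empty cell for missing values)."""
    def fmt(v) -> str:
        if isinstance(v, (float, np.floating)):
            if np.isnan(v):
                return ""
            return f"{v:.6g}"
        return str(v)

    lines = ["\t".join(df.columns)]
    for row in df.itertuples(index=False):
        lines.append("\t".join(fmt(v) for v in row))
    return "\n".join(lines) + "\n"


def write_tables(result: DIRpredResult, outdir: str | Path) -> dict[str, Path]:
    """Write the main per-site table and the two cross-score tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "scores": outdir / "dirpred_scores.tsv",
        "cross_conservation": outdir / "cross_conservation.tsv",
        "cross_coevolution": outdir / "cross_coevolution.tsv",
    }
    main = result.table().sort_values("ref_position")
    paths["scores"].write_text(format_table(main))
    cons, coev = cross_tables(result.components)
    paths["cross_conservation"].write_text(format_table(cons))
    paths["cross_coevolution"].write_text(format_table(coev))
    return paths


def render_recap(result: DIRpredResult, outdir: str | Path) -> list[Path]:
    """Per-site component/total recap plus the two cross-score scatters.

    Rendering problems raise warnings, never pipeline failures.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    c = result.components
    if c.n_sites == 0:
        warnings.warn("empty result; no recap rendered")
        return []
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        files: list[Path] = []
        fig, axes = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
        pos = c.ref_position
        bottom = np.zeros(c.n_sites)
        for name, vals in [("I", c.I), ("II", c.II_msa), ("III", c.III), ("IV", c.IV)]:
            axes[0].bar(pos, vals, bottom=bottom, label=name, width=0.8)
            bottom = bottom + vals
        axes[0].set_ylabel("stacked components")
        axes[0].legend(ncol=4, fontsize=8)
        axes[1].plot(pos, result.total_msa, marker="o", ms=3, label="total (MSA)")
        if result.total_msta is not None:
            axes[1].plot(pos, result.total_msta, marker="s", ms=3, label="total (MSTA)")
        axes[1].set_xlabel("reference position")
        axes[1].set_ylabel("combined score")
        axes[1].legend(fontsize=8)
        fig.tight_layout()
        recap = outdir / "recap.png"
        fig.savefig(recap, dpi=120)
        plt.close(fig)
        files.append(recap)

        cons, coev = cross_tables(c)
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        axes[0].scatter(
            cons["paralog_conservation_msa"], cons["ortholog_conservation"], s=12
        )
        axes[0].set_xlabel("paralog conservation")
        axes[0].set_ylabel("ortholog conservation")
        axes[1].scatter(
            coev["ligand_ligand_coevolution"],
            coev["ligand_receptor_coevolution"],
            s=12,
        )
        axes[1].set_xlabel("ligand-ligand coevolution")
        axes[1].set_ylabel("ligand-receptor coevolution")
        fig.tight_layout()
        cross = outdir / "cross_scores.png"
        fig.savefig(cross, dpi=120)
        plt.close(fig)
        files.append(cross)
        return files
    except Exception as exc:  # cosmetic layer: degrade to a warning
        warnings.warn(f"recap rendering failed: {exc}")
        return []
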