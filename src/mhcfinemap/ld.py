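"""Dosage-based linkage disequilibrium and regional association reporting.

LD is computed on allele dosages (the data the pipeline actually has
after imputation) as the squared Pearson correlation over the samples
non-missing in both markers. Regional tables serialize the nominal and
conditioned scans side by side with genome-wide significance flags
(strict p < 5e-8) and -log10(p) capped at a sentinel for underflow.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import GENOME_WIDE_P

__all__ = ["dosage_r2", "flag_significance", "regional_table", "NEGLOG10_CAP"]

#: sentinel for -log10(p) when p underflows to zero.
NEGLOG10_CAP = 320.0


def dosage_r2(a, b, min_overlap: int = 30) -> float:
    """Squared Pearson correlation between two dosage vectors.

    Computed on the overlap of non-missing samples; symmetric and
    invariant to affine rescaling of either vector. Raises if the overlap
    is below ``min_overlap``; returns NaN for a zero-variance marker.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if int(ok.sum()) < min_overlap:
        raise ValueError(f"only {int(ok.sum())} overlapping samples (< {min_overlap})")
    a, b = a[ok], b[ok]
    va, vb = a.var(), b.var()
    if va == 0.0 or vb == 0.0:
        return float("nan")
    cov = np.mean((a - a.mean()) * (b - b.mean()))
    return float(cov * cov / (va * vb))


def neglog10(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):
        out = -np.log10(p)
    return np.where(np.isfinite(out), np.minimum(out, NEGLOG10_CAP), NEGLOG10_CAP)


def flag_significance(records: pd.DataFrame, threshold: float = GENOME_WIDE_P) -> pd.DataFrame:
    """Add significance flags and -log10(p) to a results table.

    The flag is strict (p < threshold); p = 0 underflow is flagged with
    -log10(p) capped at the sentinel. Returns a copy with ``significant``
    and ``neglog10_p`` columns; per-category flag counts are stored in
    ``DataFrame.attrs['flag_counts']``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0,1)")
    out = records.copy()
    p = out["p"].to_numpy(dtype=float)
    out["significant"] = (p < threshold) & ~np.isnan(p)
    out["neglog10_p"] = neglog10(p)
    if "category" in out.columns:
        out.attrs["flag_counts"] = (
            out.loc[out["significant"], "category"].value_counts().to_dict()
        )
    return out


def regional_table(assoc: pd.DataFrame, omnibus: pd.DataFrame | None,
                   marker_info: pd.DataFrame, condition_on=(),
                   threshold: float = GENOME_WIDE_P) -> pd.DataFrame:
    """One row per tested marker or position group, ordered along the region.

    Combines the biallelic scan and the omnibus results of one marker
    table into a Manhattan-ready frame: position, category, p, -log10(p),
    significance flag and the conditioned-on list. Duplicated ids raise.
    """
    rows = assoc.copy()
    rows["category"] = marker_info.loc[rows.index, "category"]
    rows["pos"] = marker_info.loc[rows.index, "pos"]
    if omnibus is not None and len(omnibus):
        om = omnibus.copy()
        gene_pos = marker_info.loc[marker_info["aa_pos"].notna(), "pos"]
        om["category"] = "AA_position"
        om["pos"] = int(gene_pos.iloc[0]) if len(gene_pos) else np.nan
        rows = pd.concat([rows, om])
    if rows.index.has_duplicates:
        dup = rows.index[rows.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated marker ids in regional table: {dup}")
    rows["conditioned_on"] = ",".join(condition_on)
    rows = flag_significance(rows, threshold)
    cols = ["pos", "category", "p", "neglog10_p", "significant", "conditioned_on"]
    extra = [c for c in rows.columns if c not in cols]
    return rows.sort_values(["pos", "category"], kind="stable")[cols + extra]
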