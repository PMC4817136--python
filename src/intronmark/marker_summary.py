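"""Genome-wide descriptive statistics of marker sets and genetic-map tables.

Report columns are rounded half-up to the conventional printed precision
(one decimal for ratios and percentages, two for centiMorgan distances);
full precision is retained in parallel columns so nothing is lost to
rounding. Mean inter-marker distance follows the map-length/markers
convention (not length/(markers-1)).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (Python's round() is half-even)."""
    if x != x:  # NaN
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def per_gene_ratio(n_markers: int, n_genes: int) -> float:
    """Markers per gene, half-up to 1 decimal (e.g. 84634/20533 -> 4.1)."""
    return round_half_up(n_markers / n_genes, 1)


def per_mb_density(n_markers: int, chrom_len_bases: float) -> float:
    """Markers per megabase, half-up to 1 decimal."""
    return round_half_up(n_markers / (chrom_len_bases / 1e6), 1)


def census_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Marker census from per-chromosome counts.

    ``counts`` columns: seq_id, n_markers, n_genes_with_markers,
    chrom_len_mb. Appends an 'overall' row; per-gene ratio of a chromosome
    without marker-bearing genes is NA while its density is still reported.
    """
    df = counts.copy()
    required = {"seq_id", "n_markers", "n_genes_with_markers", "chrom_len_mb"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"census counts missing columns {sorted(missing)}")
    total = pd.DataFrame(
        [
            {
                "seq_id": "overall",
                "n_markers": df["n_markers"].sum(),
                "n_genes_with_markers": df["n_genes_with_markers"].sum(),
                "chrom_len_mb": df["chrom_len_mb"].sum(),
            }
        ]
    )
    df = pd.concat([df, total], ignore_index=True)
    df["markers_per_gene"] = [
        n / g if g else np.nan for n, g in zip(df["n_markers"], df["n_genes_with_markers"])
    ]
    df["markers_per_mb"] = [
        n / mb if mb else np.nan for n, mb in zip(df["n_markers"], df["chrom_len_mb"])
    ]
    df["markers_per_gene_report"] = [round_half_up(x, 1) for x in df["markers_per_gene"]]
    df["markers_per_mb_report"] = [round_half_up(x, 1) for x in df["markers_per_mb"]]
    return df


def census(
    markers: pd.DataFrame,
    gene_models: Iterable | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-chromosome and overall marker census from a marker table.

    ``markers`` needs seq_id and gene_id columns; chrom_lengths maps seq_id
    to bases. The result is permutation-invariant over marker order.
    """
    if chrom_lengths is None:
        raise ValueError("census requires chromosome lengths in bases")
    rows = []
    grouped = markers.groupby("seq_id", sort=True)
    for seq_id in sorted(chrom_lengths):
        if seq_id in grouped.groups:
            sub = grouped.get_group(seq_id)
            n_markers = len(sub)
            n_genes = sub["gene_id"].nunique()
        else:
            n_markers = n_genes = 0
        rows.append(
            {
                "seq_id": seq_id,
                "n_markers": n_markers,
                "n_genes_with_markers": n_genes,
                "chrom_len_mb": chrom_lengths[seq_id] / 1e6,
            }
        )
    return census_from_counts(pd.DataFrame(rows))


DEFAULT_FLP_BINS: tuple[tuple[int, float], ...] = (
    (1, 4),
    (5, 9),
    (10, 49),
    (50, 101),
    (102, float("inf")),
)


def flp_distribution(
    flp_values: Sequence[int] | pd.Series,
    bins: Sequence[tuple[int, float]] = DEFAULT_FLP_BINS,
) -> tuple[pd.DataFrame, float]:
    """Bin net fragment-length polymorphisms; returns (table, mean FLP).

    Percentages are over all markers, reported half-up to 1 decimal; an
    empty marker set yields an all-zero table and NaN mean.
    """
    values = np.asarray(list(flp_values), dtype=float)
    n = len(values)
    rows = []
    for lo, hi in bins:
        label = f"{lo}-{int(hi)}" if np.isfinite(hi) else f">{lo - 1}"
        count = int(((values >= lo) & (values <= hi)).sum())
        pct = 100.0 * count / n if n else 0.0
        rows.append(
            {
                "bin": label,
                "count": count,
                "pct": pct,
                "pct_report": round_half_up(pct, 1),
            }
        )
    table = pd.DataFrame(rows, columns=["bin", "count", "pct", "pct_report"])
    mean_flp = float(values.mean()) if n else float("nan")
    return table, mean_flp


def validation_summary(
    n_tested: Mapping[str, int],
    n_amplified: Mapping[str, int],
    n_polymorphic: Mapping[str, int],
) -> pd.DataFrame:
    """Amplification and polymorphism percentages per marker class.

    amplification% = amplified/tested; polymorphism% = polymorphic/amplified;
    an 'overall' row pools the classes. Ordering
    polymorphic <= amplified <= tested is enforced per class.
    """
    classes = list(n_tested)
    rows = []
    for cls in classes + ["overall"]:
        if cls == "overall":
            t = sum(n_tested.values())
            a = sum(n_amplified.values())
            p = sum(n_polymorphic.values())
        else:
            t, a, p = n_tested[cls], n_amplified.get(cls, 0), n_polymorphic.get(cls, 0)
        if not 0 <= p <= a <= t:
            raise ValueError(
                f"{cls}: requires polymorphic <= amplified <= tested, got {p},{a},{t}"
            )
        amp_pct = 100.0 * a / t if t else float("nan")
        poly_pct = 100.0 * p / a if a else float("nan")
        rows.append(
            {
                "class": cls,
                "n_tested": t,
                "n_amplified": a,
                "n_polymorphic": p,
                "amplification_pct": amp_pct,
                "amplification_pct_report": round_half_up(amp_pct, 1),
                "polymorphism_pct": poly_pct,
                "polymorphism_pct_report": round_half_up(poly_pct, 1),
            }
        )
    return pd.DataFrame(rows)


def map_saturation(map_table: pd.DataFrame) -> pd.DataFrame:
    """Mean inter-marker distance per chromosome and overall.

    ``map_table`` columns: chromosome, n_markers, map_length_cM. Mean
    distance is map length / marker count (2-decimal report rounding);
    the overall mean is total length / total markers. Zero markers -> NA.
    """
    df = map_table.copy()
    total = pd.DataFrame(
        [
            {
                "chromosome": "overall",
                "n_markers": df["n_markers"].sum(),
                "map_length_cM": df["map_length_cM"].sum(),
            }
        ]
    )
    df = pd.concat([df, total], ignore_index=True)
    df["mean_inter_marker_cM"] = [
        length / n if n else np.nan
        for n, length in zip(df["n_markers"], df["map_length_cM"])
    ]
    df["mean_inter_marker_cM_report"] = [
        round_half_up(x, 2) for x in df["mean_inter_marker_cM"]
    ]
    return df
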