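"""MRE-level expression, differential MREs and site-type composition.

The RE expression matrix is converted into an MRE expression matrix: each
(seed family x site type) row is the site-count-weighted sum of the RPKM of
the loci carrying its sites (an RE with more copies of a site can sponge
more miRNA).  A presence mode (weight 1 per locus carrying >= 1 site) is
kept for sensitivity analysis.  Differential MRE calling reuses the
two-group screen from :mod:`retroce.re_quant`.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .mre_scan import MRESite, SITE_TYPES
from .re_quant import differential_expression

__all__ = [
    "sites_to_frame",
    "site_count_table",
    "mre_expression",
    "differential_mre",
    "type_proportions",
    "top_k",
    "mre_row_id",
]


def mre_row_id(family: str, site_type: str) -> str:
    return f"{family}:{site_type}"


def sites_to_frame(sites: Sequence[MRESite]) -> pd.DataFrame:
    """Long-form table of detected sites."""
    return pd.DataFrame(
        {
            "locus_id": [s.locus_id for s in sites],
            "family": [s.mirna_family for s in sites],
            "site_type": [s.site_type for s in sites],
            "offset": [s.offset for s in sites],
        }
    )


def site_count_table(sites: Sequence[MRESite] | pd.DataFrame) -> pd.DataFrame:
    """Aggregate sites to per-(locus, family, type) counts."""
    df = sites if isinstance(sites, pd.DataFrame) else sites_to_frame(sites)
    if df.empty:
        return pd.DataFrame(columns=["locus_id", "family", "site_type", "n_sites"])
    return (
        df.groupby(["locus_id", "family", "site_type"])
        .size()
        .rename("n_sites")
        .reset_index()
    )


def mre_expression(
    re_expr: pd.DataFrame,
    site_counts: pd.DataFrame,
    mode: str = "count_weighted",
) -> pd.DataFrame:
    """Convert RE expression into MRE expression.

    ``count_weighted``: value(family, type, sample) = sum over loci of
    n_sites x RPKM(locus, sample).  ``presence``: each locus carrying >= 1
    site contributes its RPKM once.  Rows are ``family:type`` identifiers;
    the weighting mode is recorded in ``DataFrame.attrs["weighting_mode"]``.
    """
    if mode not in {"count_weighted", "presence"}:
        raise ValueError(f"unknown weighting mode {mode!r}")
    counts = site_count_table(site_counts) if not isinstance(site_counts, pd.DataFrame) else site_counts
    if not set(counts.columns) >= {"locus_id", "family", "site_type", "n_sites"}:
        counts = site_count_table(counts)
    unknown = set(counts["locus_id"]) - set(re_expr.index)
    if unknown:
        raise KeyError(f"site table names loci absent from the expression matrix: {sorted(unknown)[:5]}")
    weights = counts.copy()
    if mode == "presence":
        weights["n_sites"] = 1
    w = weights.pivot_table(
        index=["family", "site_type"], columns="locus_id", values="n_sites",
        aggfunc="sum", fill_value=0,
    )
    if w.empty:
        out = pd.DataFrame(columns=re_expr.columns)
    else:
        values = w.to_numpy() @ re_expr.reindex(w.columns).to_numpy()
        out = pd.DataFrame(
            values,
            index=[mre_row_id(f, t) for f, t in w.index],
            columns=re_expr.columns,
        )
    out.attrs["weighting_mode"] = mode
    return out


def differential_mre(
    mre_expr: pd.DataFrame,
    groups: Mapping[str, str],
    alpha: float = 0.05,
    fc_threshold: float = 1.0,
    pseudocount: float = 0.25,
) -> pd.DataFrame:
    """Two-group differential screen on MRE rows (same contract as for REs)."""
    return differential_expression(
        mre_expr, groups, alpha=alpha, fc_threshold=fc_threshold, pseudocount=pseudocount
    )


def type_proportions(
    sites: Sequence[MRESite] | pd.DataFrame, ndigits: int = 1
) -> dict[str, float]:
    """Percentage of site records per binding type over all detected sites."""
    df = sites if isinstance(sites, pd.DataFrame) else sites_to_frame(sites)
    if df.empty:
        raise ValueError("cannot compute type proportions of an empty site set")
    counts = df["site_type"].value_counts()
    total = counts.sum()
    return {t: round(100.0 * counts.get(t, 0) / total, ndigits) for t in SITE_TYPES}


def top_k(diff: pd.DataFrame, k: int, direction: str = "up") -> pd.DataFrame:
    """Top-k significant rows by |log2fc| in one direction.

    Ties are broken by p-value ascending then feature id; fewer than ``k``
    rows are returned when the table runs out.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if direction not in {"up", "down"}:
        raise ValueError(f"direction must be up or down, got {direction!r}")
    sig = diff[diff["significant"]]
    sig = sig[sig["log2fc"] > 0] if direction == "up" else sig[sig["log2fc"] < 0]
    sig = sig.reset_index(names="feature")
    sig["_absfc"] = sig["log2fc"].abs()
    sig = sig.sort_values(["_absfc", "p_value", "feature"], ascending=[False, True, True])
    return sig.drop(columns="_absfc").set_index("feature").head(k)
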