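"""Transect-level summaries and the distance/orchard analysis.

Works on the bee-level table produced by deconvolution (or the
ground-truth table from the simulator): per-row category percentages,
cross-pollen source composition among cross-carrying bees, and the
binomial mixed-model test of distance and orchard-design effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glmm import GlmmFit, fit_glmm

__all__ = [
    "summarize_proportions",
    "summarize_cross_sources",
    "distance_effect_report",
    "DistanceEffectReport",
    "plot_proportions",
]

_CATEGORIES = ("CROSS_ONLY", "MIXED", "SELF_ONLY")


def _require_included(records: pd.DataFrame) -> pd.DataFrame:
    if records.empty:
        raise ValueError("no included bees")
    if "included" in records.columns:
        records = records.loc[records["included"].astype(bool)]
    else:
        records = records.loc[records["score"].notna()]
    if records.empty:
        raise ValueError("no included bees")
    return records


def summarize_proportions(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Category percentages per orchard x row, with per-transect breakdown.

    Percentages are of *included* (non-UNDETERMINED) bees and sum to 100
    within each orchard x row cell; ``pct_carrying_cross`` is the share
    capable of cross-pollination (CROSS_ONLY + MIXED).  Returns
    ``{"by_row": ..., "by_transect": ..., "row_means": ...}`` where
    ``row_means`` aggregates the per-transect percentages into an
    across-transect mean with its standard error.
    """
    included = _require_included(records)
    n_excluded = len(records) - len(included)

    def _table(group_cols: list[str]) -> pd.DataFrame:
        counts = (
            included.groupby(group_cols + ["category"], observed=True)
            .size()
            .unstack("category", fill_value=0)
            .reindex(columns=list(_CATEGORIES), fill_value=0)
        )
        n = counts.sum(axis=1)
        pct = counts.div(n, axis=0) * 100.0
        out = pct.rename(columns={c: f"pct_{c.lower()}" for c in _CATEGORIES})
        out.insert(0, "n", n)
        out["pct_carrying_cross"] = out["pct_cross_only"] + out["pct_mixed"]
        return out.reset_index()

    by_row = _table(["orchard_type", "row_index"])
    by_transect = _table(["orchard_type", "transect_id", "row_index"])
    row_means = (
        by_transect.groupby(["orchard_type", "row_index"], observed=True)[
            "pct_carrying_cross"
        ]
        .agg(mean_pct_carrying_cross="mean",
             se_pct_carrying_cross=lambda s: s.std(ddof=1) / np.sqrt(len(s)),
             n_transects="size")
        .reset_index()
    )
    by_row.attrs["n_excluded_undetermined"] = n_excluded
    return {"by_row": by_row, "by_transect": by_transect, "row_means": row_means}


def summarize_cross_sources(records: pd.DataFrame) -> pd.DataFrame:
    """Composition of cross-pollen among cross-carrying bees.

    Per orchard x host cultivar: the share of cross-carrying bees with
    exactly one cross cultivar, and the frequency of each cross cultivar
    (a bee carrying k cross cultivars contributes to k cultivar rows, so
    cultivar percentages can sum past 100).  Empty when no bee carries
    cross-pollen.
    """
    included = _require_included(records)
    cross = included.loc[included["score"] == 1].copy()
    if cross.empty:
        out = pd.DataFrame(columns=["orchard_type", "host_cultivar",
                                    "cross_cultivar", "n_cross_bees",
                                    "pct_of_cross_bees", "pct_one_cultivar"])
        out.attrs["notice"] = "no cross-carrying bees"
        return out
    cross["cross_list"] = cross["cross_cultivars"].fillna("").map(
        lambda s: [c for c in str(s).split(";") if c]
    )
    rows = []
    for (orchard, host), sub in cross.groupby(
        ["orchard_type", "host_cultivar"], observed=True
    ):
        n = len(sub)
        one = float((sub["cross_list"].map(len) == 1).mean() * 100.0)
        counts: dict[str, int] = {}
        for lst in sub["cross_list"]:
            for c in lst:
                counts[c] = counts.get(c, 0) + 1
        for cultivar, k in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
            rows.append({
                "orchard_type": orchard, "host_cultivar": host,
                "cross_cultivar": cultivar, "n_cross_bees": n,
                "pct_of_cross_bees": 100.0 * k / n,
                "pct_one_cultivar": one,
            })
    return pd.DataFrame(rows)


@dataclass
class DistanceEffectReport:
    """Human-readable + tabular verdict on distance and orchard effects."""

    alpha: float
    table: pd.DataFrame
    sigma_transect: float
    n_bees: int
    n_transects: int
    n_excluded: int

    def to_text(self) -> str:
        lines = [
            f"binomial GLMM of cross-pollen carriage "
            f"(n = {self.n_bees} bees, {self.n_transects} transects, "
            f"{self.n_excluded} excluded as undetermined)",
            f"random transect intercept SD: {self.sigma_transect:.3f}",
            f"significance threshold: p < {self.alpha:g}",
        ]
        for _, r in self.table.iterrows():
            verdict = "significant" if r["significant"] else "not significant"
            lines.append(
                f"  {r['term']}: estimate = {r['estimate']:.3f}, "
                f"s.e. = {r['se']:.3f}, p = {r['p']:.3g} -> {verdict}"
            )
        return "\n".join(lines)


def distance_effect_report(fit: GlmmFit, alpha: float = 0.05) -> DistanceEffectReport:
    """Report coefficient significance at level ``alpha`` (Wald tests)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not fit.converged:
        raise RuntimeError(
            "refusing to report an unconverged fit; diagnostics: "
            + "; ".join(fit.warnings)
        )
    table = fit.summary_frame()
    table["significant"] = table["p"] < alpha
    return DistanceEffectReport(
        alpha=alpha, table=table, sigma_transect=fit.sigma_transect,
        n_bees=fit.n_obs, n_transects=fit.n_groups, n_excluded=fit.n_excluded,
    )


def analyze_transects(
    records: pd.DataFrame, alpha: float = 0.05
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, GlmmFit, DistanceEffectReport]:
    """One-call analysis layer: proportions, sources, GLMM, report."""
    proportions = summarize_proportions(records)
    sources = summarize_cross_sources(records)
    fit = fit_glmm(records)
    report = distance_effect_report(fit, alpha=alpha)
    return proportions, sources, fit, report


def plot_proportions(by_row: pd.DataFrame, path) -> None:
    """Stacked-bar chart of category percentages per orchard x row."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    orchards = list(by_row["orchard_type"].unique())
    fig, axes = plt.subplots(1, len(orchards), figsize=(5 * len(orchards), 4),
                             squeeze=False)
    colors = {"pct_cross_only": "#1b7837", "pct_mixed": "#a6dba0",
              "pct_self_only": "#c2a5cf"}
    labels = {"pct_cross_only": "cross-pollen only", "pct_mixed": "cross + self",
              "pct_self_only": "self-pollen only"}
    for ax, orchard in zip(axes[0], orchards):
        sub = by_row.loc[by_row["orchard_type"] == orchard]
        x = np.arange(len(sub))
        bottom = np.zeros(len(sub))
        for col in ("pct_cross_only", "pct_mixed", "pct_self_only"):
            ax.bar(x, sub[col], bottom=bottom, color=colors[col],
                   label=labels[col])
            bottom += sub[col].to_numpy()
        ax.set_xticks(x, [f"row {r}" for r in sub["row_index"]])
        ax.set_ylabel("% of honey bees")
        ax.set_title(f"{orchard} orchard")
    axes[0][0].legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
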