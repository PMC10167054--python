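"""Cohort-level statistics and reporting.

Operates on the per-subject feature table (one row per subject x side x
force): paired t-tests across force levels, one-way ANOVA across groups,
and Pearson cross-modal correlations between EMG complexity (fApEn) and
hemodynamic / network measures. All tests are two-sided at alpha = 0.05;
Benjamini-Hochberg FDR is applied within each declared family (the strata
of one comparison, or one correlation panel set) and every reported p
carries its family size.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "paired_compare",
    "anova_oneway",
    "cross_modal_correlation",
    "permutation_paired_pvalue",
    "report",
]


def _fdr(df: pd.DataFrame, q: float) -> pd.DataFrame:
    finite = df["p"].notna().to_numpy()
    qv = np.full(len(df), np.nan)
    rej = np.zeros(len(df), dtype=bool)
    if finite.any():
        rej[finite], qv[finite], *_ = multipletests(df.loc[finite, "p"], alpha=q, method="fdr_bh")
    df = df.copy()
    df["q"] = qv
    df["significant"] = rej
    df["family_size"] = int(finite.sum())
    return df


def paired_compare(
    table: pd.DataFrame,
    metric: str,
    factor: str = "force",
    subject_col: str = "subject",
    strata: tuple[str, ...] = ("side",),
    q: float = 0.05,
) -> pd.DataFrame:
    """Paired t-test of ``metric`` between the two levels of ``factor``
    within each stratum, FDR-corrected across strata.

    Rows without a partner at the other factor level are dropped with a
    recorded count. Returns one row per stratum: t, df, p, q, mean
    difference (high - low level) with 95% CI.
    """
    levels = sorted(table[factor].unique())
    if len(levels) != 2:
        raise ValueError(f"paired_compare needs exactly 2 levels of {factor!r}")
    lo, hi = levels
    rows = []
    grouped = table.groupby(list(strata)) if strata else [((), table)]
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        wide = sub.pivot_table(index=subject_col, columns=factor, values=metric)
        n_dropped = int(wide.isna().any(axis=1).sum())
        wide = wide.dropna()
        n = len(wide)
        if n < 2:
            raise ValueError(f"stratum {key}: need >= 2 paired subjects, got {n}")
        d = wide[hi] - wide[lo]
        t, p = sp_stats.ttest_rel(wide[hi], wide[lo])
        se = d.std(ddof=1) / np.sqrt(n)
        tcrit = sp_stats.t.ppf(0.975, n - 1)
        rows.append(
            {
                **{s: v for s, v in zip(strata, key)},
                "metric": metric,
                "n_pairs": n,
                "n_dropped": n_dropped,
                "mean_diff": float(d.mean()),
                "ci_low": float(d.mean() - tcrit * se),
                "ci_high": float(d.mean() + tcrit * se),
                "t": float(t),
                "df": n - 1,
                "p": float(p),
            }
        )
    return _fdr(pd.DataFrame(rows), q)


def permutation_paired_pvalue(
    a: np.ndarray, b: np.ndarray, n_perm: int = 2000, seed: int = 0
) -> float:
    """Sign-flip permutation p-value for a paired comparison (fallback when
    normality is in doubt)."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    rng = np.random.default_rng(seed)
    obs = abs(d.mean())
    flips = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
    null = np.abs((flips * d).mean(axis=1))
    return float((1 + np.sum(null >= obs - 1e-15)) / (1 + n_perm))


def anova_oneway(
    table: pd.DataFrame, metric: str, group_col: str
) -> tuple[float, float]:
    """Standard one-way ANOVA of ``metric`` across the levels of ``group_col``."""
    groups = [g[metric].dropna().to_numpy() for _, g in table.groupby(group_col)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 observations each")
    F, p = sp_stats.f_oneway(*groups)
    return float(F), float(p)


def cross_modal_correlation(
    table: pd.DataFrame,
    x: str = "fapen_bic",
    y_cols: list[str] | None = None,
    strata: tuple[str, ...] = ("side",),
    q: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of the EMG complexity measure against each
    hemodynamic/network column, per stratum, FDR over the whole panel.

    Rows pool subjects and force levels within each stratum (matched rows
    only). Returns r, p, q, n per (stratum, y) pair.
    """
    if y_cols is None:
        y_cols = [c for c in table.columns if c.startswith("integral_")]
    rows = []
    grouped = table.groupby(list(strata)) if strata else [((), table)]
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        for y in y_cols:
            pair = sub[[x, y]].dropna()
            n = len(pair)
            if n < 3:
                raise ValueError(f"stratum {key}, pair ({x}, {y}): need n >= 3, got {n}")
            r, p = sp_stats.pearsonr(pair[x], pair[y])
            rows.append(
                {
                    **{s: v for s, v in zip(strata, key)},
                    "x": x,
                    "y": y,
                    "n": n,
                    "r": float(r),
                    "p": float(p),
                }
            )
    return _fdr(pd.DataFrame(rows), q)


# ---------------------------------------------------------------------------
# reporting


def report(
    out_dir: str | Path,
    features: pd.DataFrame | None = None,
    paired_results: dict[str, pd.DataFrame] | None = None,
    correlations: pd.DataFrame | None = None,
    fc_matrices: dict[str, np.ndarray] | None = None,
    edge_comparisons: dict[str, pd.DataFrame] | None = None,
) -> dict[str, Path]:
    """Write figures and TSV summaries for the completed analyses.

    Missing analyses are skipped with a notice in ``report_summary.txt``;
    every number shown in a figure is also emitted as a TSV. Output is
    deterministic for identical inputs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    notes: list[str] = []

    def save_tsv(name: str, df: pd.DataFrame) -> None:
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written[name] = path

    if features is not None and len(features):
        save_tsv("features", features)
        for metric in ("fapen_bic", "fapen_tri", "cci"):
            if metric not in features.columns:
                continue
            fig, ax = plt.subplots(figsize=(5, 4))
            pivots = []
            labels = []
            for side in sorted(features["side"].unique()):
                for force in sorted(features["force"].unique()):
                    vals = features.query("side == @side and force == @force")[metric].dropna()
                    pivots.append(vals)
                    labels.append(f"{side[:3]} {int(force * 100)}%")
            ax.boxplot(pivots, tick_labels=labels)
            ax.set_ylabel(metric)
            ax.set_title(f"{metric} by condition")
            fig.tight_layout()
            path = out_dir / f"box_{metric}.png"
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written[f"box_{metric}"] = path
    else:
        notes.append("no feature table: condition comparisons skipped")

    if paired_results:
        for name, df in paired_results.items():
            save_tsv(f"paired_{name}", df)
    else:
        notes.append("no paired analyses")

    if correlations is not None and len(correlations):
        save_tsv("correlations", correlations)
        if features is not None:
            top = correlations.dropna(subset=["p"]).sort_values("p").head(4)
            for _, row in top.iterrows():
                sub = features
                if "side" in row and "side" in features.columns:
                    sub = features[features["side"] == row["side"]]
                pair = sub[[row["x"], row["y"]]].dropna()
                fig, ax = plt.subplots(figsize=(4.5, 4))
                ax.scatter(pair[row["x"]], pair[row["y"]], s=18)
                if len(pair) >= 2:
                    coef = np.polyfit(pair[row["x"]], pair[row["y"]], 1)
                    xs = np.linspace(pair[row["x"]].min(), pair[row["x"]].max(), 50)
                    ax.plot(xs, np.polyval(coef, xs), "r-")
                ax.set_xlabel(row["x"])
                ax.set_ylabel(row["y"])
                ax.set_title(f"r={row['r']:.3f}, p={row['p']:.2g}")
                fig.tight_layout()
                name = f"scatter_{row.get('side', 'all')}_{row['y']}"
                path = out_dir / f"{name}.png"
                fig.savefig(path, dpi=100)
                plt.close(fig)
                written[name] = path
    else:
        notes.append("no correlation analyses")

    if fc_matrices:
        for name, mat in sorted(fc_matrices.items()):
            fig, ax = plt.subplots(figsize=(4.5, 4))
            im = ax.imshow(np.asarray(mat), vmin=-1, vmax=1, cmap="RdBu_r")
            fig.colorbar(im, ax=ax)
            ax.set_title(name)
            fig.tight_layout()
            path = out_dir / f"fc_{name}.png"
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written[f"fc_{name}"] = path
            save_tsv(f"fc_{name}", pd.DataFrame(np.asarray(mat)))
    else:
        notes.append("no connectivity matrices")

    if edge_comparisons:
        for name, df in edge_comparisons.items():
            save_tsv(f"edges_{name}", df)
    else:
        notes.append("no edge comparisons")

    summary = out_dir / "report_summary.txt"
    lines = [f"written: {name}" for name in sorted(written)]
    lines += [f"notice: {n}" for n in notes]
    summary.write_text("\n".join(lines) + "\n")
    written["summary"] = summary
    return written
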