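"""Nonparametric group comparison and correlation-matrix PCA.

The analysis battery mirrors the statistics used for group choice assays:
Kruskal–Wallis omnibus tests with Dunn's rank-based post-hoc, Shapiro–Wilk
normality and Levene variance-homogeneity checks, a strict significance
threshold (p < 0.005 by default), and a standardized PCA on the correlation
matrix retaining components with eigenvalue >= 1.

:func:`run_paper_analyses` chains the synthetic generators, the choice
indices, the fractionation fits, the trajectory metrics and these tests
into one reproducible report bundle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from . import fractionation, metrics as tm, synthetic
from .indices import CPPTubeCounts, compute_ci, compute_pi
from .synthetic import PopulationModel, as_rng

__all__ = [
    "DEFAULT_THRESHOLD",
    "GroupedSamples",
    "TestReport",
    "PCAResult",
    "AnalysisConfig",
    "ReportBundle",
    "kruskal_wallis",
    "posthoc_ranks",
    "levene",
    "shapiro_wilk",
    "pca_correlation",
    "run_paper_analyses",
]

#: Significance threshold applied uniformly across the battery.
DEFAULT_THRESHOLD = 0.005


@dataclass
class GroupedSamples:
    """Labelled groups of numeric values; NaNs are excluded and counted."""

    groups: dict[str, np.ndarray]
    metric: str = ""
    units: str = ""
    n_missing: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[float]],
                     metric: str = "", units: str = "") -> "GroupedSamples":
        groups, missing = {}, {}
        for label, values in mapping.items():
            arr = np.asarray(list(values), dtype=float)
            ok = ~np.isnan(arr)
            groups[str(label)] = arr[ok]
            missing[str(label)] = int((~ok).sum())
        return cls(groups, metric=metric, units=units, n_missing=missing)


def _coerce(data) -> GroupedSamples:
    if isinstance(data, GroupedSamples):
        return data
    return GroupedSamples.from_mapping(data)


@dataclass
class TestReport:
    """Outcome of one statistical test."""

    test: str
    statistic: float
    pvalue: float
    df: float | tuple | None = None
    threshold: float = DEFAULT_THRESHOLD
    extras: dict = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None

    @property
    def significant(self) -> bool:
        return self.pvalue < self.threshold

    def to_dict(self) -> dict:
        d = {"test": self.test, "statistic": self.statistic,
             "pvalue": self.pvalue, "df": self.df,
             "threshold": self.threshold, "significant": self.significant}
        d.update(self.extras)
        return d


def _validated_groups(data: GroupedSamples, min_groups: int = 2) -> list[np.ndarray]:
    if len(data.groups) < min_groups:
        raise ValueError(f"need at least {min_groups} groups")
    arrays = []
    for label, arr in data.groups.items():
        if arr.size == 0:
            raise ValueError(f"group {label!r} has no valid values")
        arrays.append(arr)
    return arrays


def kruskal_wallis(data, threshold: float = DEFAULT_THRESHOLD) -> TestReport:
    """Kruskal–Wallis H test with mid-rank tie correction.

    The chi-square reference uses (number of groups - 1) degrees of
    freedom.  When every value in every group is identical the statistic
    is 0 by convention (no rank variation) with p = 1.
    """
    data = _coerce(data)
    arrays = _validated_groups(data)
    pooled = np.concatenate(arrays)
    df = len(arrays) - 1
    if np.ptp(pooled) == 0:
        return TestReport("kruskal-wallis", 0.0, 1.0, df, threshold)
    h, p = _st.kruskal(*arrays)
    return TestReport("kruskal-wallis", float(h), float(p), df, threshold,
                      extras={"n_per_group": [int(a.size) for a in arrays]})


def posthoc_ranks(data, method: str = "dunn",
                  threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Dunn's pairwise z tests on the joint mid-ranks, with tie correction.

    Returns one row per unordered pair with the z statistic, the unadjusted
    two-sided normal p-value and its Bonferroni adjustment.
    """
    if method != "dunn":
        raise ValueError("only Dunn's test is implemented")
    data = _coerce(data)
    arrays = _validated_groups(data)
    labels = list(data.groups.keys())
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = _st.rankdata(pooled)
    # tie correction term: sum over tie groups of (t^3 - t)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))

    mean_ranks, sizes = [], []
    start = 0
    for arr in arrays:
        mean_ranks.append(float(ranks[start:start + arr.size].mean()))
        sizes.append(arr.size)
        start += arr.size

    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    rows = []
    m = len(arrays) * (len(arrays) - 1) // 2
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * _st.norm.sf(abs(z))
            rows.append({
                "group1": labels[i], "group2": labels[j], "z": z,
                "p_unadjusted": p, "p_bonferroni": min(1.0, p * m),
                "significant": min(1.0, p * m) < threshold,
            })
    return pd.DataFrame(rows)


def levene(data, center: str = "median",
           threshold: float = DEFAULT_THRESHOLD) -> TestReport:
    """Levene's homogeneity-of-variance test (Brown–Forsythe when
    ``center='median'``, the robust default)."""
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    data = _coerce(data)
    arrays = _validated_groups(data)
    for arr in arrays:
        if arr.size < 2:
            raise ValueError("Levene's test needs >= 2 values per group")
    stat, p = _st.levene(*arrays, center=center)
    k, n = len(arrays), sum(a.size for a in arrays)
    return TestReport("levene", float(stat), float(p), (k - 1, n - k),
                      threshold, extras={"center": center})


def shapiro_wilk(values, threshold: float = DEFAULT_THRESHOLD) -> TestReport:
    """Shapiro–Wilk normality test on one sample."""
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 3:
        raise ValueError("Shapiro–Wilk needs at least 3 values")
    stat, p = _st.shapiro(arr)
    return TestReport("shapiro-wilk", float(stat), float(p), None, threshold)


@dataclass
class PCAResult:
    """Standardized PCA of a samples x variables table.

    Eigenvalues of the correlation matrix (non-increasing), the
    eigenvectors and the correlation loadings (eigenvector *
    sqrt(eigenvalue)); components with eigenvalue >= ``min_eigenvalue``
    are retained.  Sign convention: the largest-magnitude loading of each
    component is positive.
    """

    eigenvalues: np.ndarray
    eigenvectors: pd.DataFrame
    loadings: pd.DataFrame
    scores: pd.DataFrame
    proportion: np.ndarray
    retained: int
    min_eigenvalue: float = 1.0
    n_dropped_rows: int = 0

    def retained_loadings(self) -> pd.DataFrame:
        return self.loadings.iloc[:, :self.retained]


def pca_correlation(table: pd.DataFrame,
                    min_eigenvalue: float = 1.0,
                    dropna: bool = True) -> PCAResult:
    """PCA on the correlation matrix of ``table`` (samples x variables)."""
    df = pd.DataFrame(table)
    if df.shape[1] < 2:
        raise ValueError("PCA needs at least two variables")
    n0 = len(df)
    if dropna:
        df = df.dropna()
    n_dropped = n0 - len(df)
    if len(df) < 3:
        raise ValueError("PCA needs at least three complete samples")
    X = df.to_numpy(dtype=float)
    std = X.std(axis=0, ddof=1)
    for col, s in zip(df.columns, std):
        if s == 0 or not np.isfinite(s):
            raise ValueError(f"variable {col!r} is constant; cannot standardize")
    Z = (X - X.mean(axis=0)) / std
    corr = Z.T @ Z / (len(df) - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    loadings = evecs * np.sqrt(evals)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(evecs.shape[1]):
        pivot = np.argmax(np.abs(loadings[:, j]))
        if loadings[pivot, j] < 0:
            evecs[:, j] *= -1.0
            loadings[:, j] *= -1.0
    pcs = [f"PC{j + 1}" for j in range(evecs.shape[1])]
    return PCAResult(
        eigenvalues=evals,
        eigenvectors=pd.DataFrame(evecs, index=df.columns, columns=pcs),
        loadings=pd.DataFrame(loadings, index=df.columns, columns=pcs),
        scores=pd.DataFrame(Z @ evecs, index=df.index, columns=pcs),
        proportion=evals / evals.size,
        retained=int(np.sum(evals >= min_eigenvalue)),
        min_eigenvalue=min_eigenvalue,
        n_dropped_rows=n_dropped,
    )


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class AnalysisConfig:
    """Study conditions for one end-to-end synthetic reproduction run."""

    model: PopulationModel
    seed: int = 0
    group_sizes: tuple[int, ...] = (20, 40, 60, 80, 100)
    size_replicates: int = 10
    day_count: int = 4
    day_groups: int = 10
    n_flies: int = 80
    retest_replicates: int = 8
    minimum_pool: int = 40
    fit_sessions: int = 8
    buridan_per_tube: int = 13
    buridan_params: synthetic.BuridanSimParams = field(
        default_factory=synthetic.BuridanSimParams)
    cpp_params: synthetic.CPPParams = field(default_factory=synthetic.CPPParams)
    tmaze_params: synthetic.TMazeParams = field(
        default_factory=synthetic.TMazeParams)
    threshold: float = DEFAULT_THRESHOLD
    include_buridan: bool = True
    outdir: Path | None = None


@dataclass
class ReportBundle:
    """All tables and test reports produced by one reproduction run."""

    config: AnalysisConfig
    group_size_test: TestReport
    group_size_levene: TestReport
    day_test: TestReport
    tmaze_retest_test: TestReport
    cpp_retest_test: TestReport
    cpp_retest_means: dict[int, float]
    tube_counts: CPPTubeCounts
    fit_binomial: fractionation.ModelFit
    fit_betabinomial: fractionation.ModelFit
    buridan_tests: dict[str, TestReport]
    metrics_table: pd.DataFrame | None
    pca: PCAResult | None
    tables: dict[str, pd.DataFrame]

    @property
    def preferred_model(self) -> str:
        return ("binomial"
                if self.fit_binomial.aic <= self.fit_betabinomial.aic
                else "betabinomial")


def _ci_sessions(model, size, reps, rng, params) -> list[float]:
    out = []
    for _ in range(reps):
        flies = synthetic.sample_population(model, size, rng)
        p = synthetic.TMazeParams(n_flies=size,
                                  elevator_capture_prob=params.elevator_capture_prob)
        out.append(compute_ci(synthetic.simulate_tmaze(flies, p, rng).session))
    return out


def simulate_buridan_cohort(model: PopulationModel,
                            per_tube: int,
                            rng,
                            cpp_params: synthetic.CPPParams,
                            buridan_params: synthetic.BuridanSimParams,
                            n_flies: int = 80,
                            max_sessions: int = 200) -> pd.DataFrame:
    """Fractionate flies by CPP tube, run each through the Buridan arena,
    and return the metrics table with a ``light_choices`` column."""
    n_tubes = cpp_params.n_choices + 1
    chosen: dict[int, list] = {k: [] for k in range(n_tubes)}
    sessions = 0
    while (sessions < max_sessions
           and any(len(chosen[k]) < per_tube for k in range(n_tubes))):
        cohort = synthetic.sample_population(model, n_flies, rng)
        out = synthetic.simulate_cpp(cohort, cpp_params, rng)
        for fly, tube in zip(out.flies, out.tubes):
            k = int(tube)
            if len(chosen[k]) < per_tube:
                chosen[k].append(fly)
        sessions += 1
    rows = []
    for k in range(n_tubes):
        for fly in chosen[k]:
            traj = synthetic.simulate_buridan(fly, params=buridan_params, seed=rng)
            rec = tm.compute_all_metrics(traj, tube=k)
            row = rec.to_dict()
            row["light_choices"] = k
            rows.append(row)
    return pd.DataFrame(rows)


def run_paper_analyses(config: AnalysisConfig) -> ReportBundle:
    """Run the full synthetic analysis battery.

    Stages: group-size CI comparison with a variance test; repeated-day
    CI comparison; T-maze subgroup retest; CPP subgroup retest with
    per-tube second-session PIs; binomial vs beta-binomial fits of pooled
    first-session tube counts; Buridan metric comparisons across tubes;
    and the PCA of light choices plus the eight metrics.
    """
    rng = as_rng(config.seed)
    model = config.model
    thr = config.threshold
    tables: dict[str, pd.DataFrame] = {}

    # group-size comparison (CI by cohort size) + variance homogeneity
    by_size = {
        str(size): _ci_sessions(model, size, config.size_replicates, rng,
                                config.tmaze_params)
        for size in config.group_sizes
    }
    gs = GroupedSamples.from_mapping(by_size, metric="CI")
    group_size_test = kruskal_wallis(gs, thr)
    group_size_levene = levene(gs, threshold=thr)
    tables["ci_by_group_size"] = pd.DataFrame(
        [(k, v) for k, vals in by_size.items() for v in vals],
        columns=["group_size", "ci"])

    # same cohorts re-tested on consecutive days (traits persist)
    cohorts = [synthetic.sample_population(model, config.n_flies, rng)
               for _ in range(config.day_groups)]
    by_day = {}
    for day in range(config.day_count):
        by_day[f"day{day + 1}"] = [
            compute_ci(synthetic.simulate_tmaze(
                c, config.tmaze_params, rng).session)
            for c in cohorts
        ]
    day_test = kruskal_wallis(by_day, thr)
    tables["ci_by_day"] = pd.DataFrame(
        [(k, v) for k, vals in by_day.items() for v in vals],
        columns=["day", "ci"])

    # T-maze split-and-retest
    tr = synthetic.simulate_retest_protocol(
        model, "tmaze", config.retest_replicates, rng,
        n_flies=config.n_flies, minimum=config.minimum_pool,
        tmaze_params=config.tmaze_params)
    tmaze_groups = {
        "original": tr.values("original"),
        "bright": tr.values("bright"),
        "dark_elevator": tr.values("dark_elevator"),
    }
    tmaze_groups = {k: v for k, v in tmaze_groups.items() if v}
    tmaze_retest_test = kruskal_wallis(tmaze_groups, thr)
    tmaze_retest_test.posthoc = posthoc_ranks(tmaze_groups, threshold=thr)

    # CPP split-and-retest across the six tubes
    cr = synthetic.simulate_retest_protocol(
        model, "cpp", config.retest_replicates, rng,
        n_flies=config.n_flies, minimum=config.minimum_pool,
        cpp_params=config.cpp_params)
    n_tubes = config.cpp_params.n_choices + 1
    cpp_groups = {f"tube_{k}": cr.values(f"tube_{k}") for k in range(n_tubes)}
    cpp_groups = {k: v for k, v in cpp_groups.items() if v}
    cpp_retest_test = kruskal_wallis(cpp_groups, thr)
    cpp_retest_test.posthoc = posthoc_ranks(cpp_groups, threshold=thr)
    cpp_retest_means = {
        int(k.split("_")[1]): float(np.mean(v)) for k, v in cpp_groups.items()
    }
    tables["cpp_retest"] = pd.DataFrame(
        [(k, v) for k, vals in cpp_groups.items() for v in vals],
        columns=["first_tube", "second_pi"])

    # pooled first-session tube counts and the two model fits
    counts = np.zeros(n_tubes, dtype=int)
    for _ in range(config.fit_sessions):
        cohort = synthetic.sample_population(model, config.n_flies, rng)
        out = synthetic.simulate_cpp(cohort, config.cpp_params, rng)
        counts += np.asarray(out.counts.counts)
    tube_counts = CPPTubeCounts(tuple(int(c) for c in counts), int(counts.sum()))
    fit_bin = fractionation.fit_tube_model(tube_counts, "binomial")
    fit_bb = fractionation.fit_tube_model(tube_counts, "betabinomial")

    # Buridan metrics by tube + PCA
    buridan_tests: dict[str, TestReport] = {}
    metrics_table = None
    pca = None
    if config.include_buridan:
        metrics_table = simulate_buridan_cohort(
            model, config.buridan_per_tube, rng,
            config.cpp_params, config.buridan_params, config.n_flies)
        tables["buridan_metrics"] = metrics_table
        for metric in tm.METRIC_COLUMNS:
            grouped = {
                str(k): sub[metric].to_numpy()
                for k, sub in metrics_table.groupby("light_choices")
            }
            buridan_tests[metric] = kruskal_wallis(
                GroupedSamples.from_mapping(grouped, metric=metric), thr)
        pca = pca_correlation(
            metrics_table[["light_choices"] + tm.METRIC_COLUMNS])

    bundle = ReportBundle(
        config=config,
        group_size_test=group_size_test,
        group_size_levene=group_size_levene,
        day_test=day_test,
        tmaze_retest_test=tmaze_retest_test,
        cpp_retest_test=cpp_retest_test,
        cpp_retest_means=cpp_retest_means,
        tube_counts=tube_counts,
        fit_binomial=fit_bin,
        fit_betabinomial=fit_bb,
        buridan_tests=buridan_tests,
        metrics_table=metrics_table,
        pca=pca,
        tables=tables,
    )
    if config.outdir is not None:
        _write_bundle(bundle, Path(config.outdir))
    return bundle


def _write_bundle(bundle: ReportBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    report = {
        "group_size_test": bundle.group_size_test.to_dict(),
        "group_size_levene": bundle.group_size_levene.to_dict(),
        "day_test": bundle.day_test.to_dict(),
        "tmaze_retest_test": bundle.tmaze_retest_test.to_dict(),
        "cpp_retest_test": bundle.cpp_retest_test.to_dict(),
        "cpp_retest_mean_pi": bundle.cpp_retest_means,
        "tube_counts": list(bundle.tube_counts.counts),
        "fit_binomial": {**bundle.fit_binomial.params,
                         "loglik": bundle.fit_binomial.loglik,
                         "aic": bundle.fit_binomial.aic},
        "fit_betabinomial": {**bundle.fit_betabinomial.params,
                             "loglik": bundle.fit_betabinomial.loglik,
                             "aic": bundle.fit_betabinomial.aic},
        "preferred_model": bundle.preferred_model,
        "buridan_tests": {k: v.to_dict() for k, v in bundle.buridan_tests.items()},
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    if bundle.tmaze_retest_test.posthoc is not None:
        bundle.tmaze_retest_test.posthoc.to_csv(
            outdir / "tmaze_retest_posthoc.csv", index=False)
    if bundle.cpp_retest_test.posthoc is not None:
        bundle.cpp_retest_test.posthoc.to_csv(
            outdir / "cpp_retest_posthoc.csv", index=False)
    if bundle.pca is not None:
        bundle.pca.loadings.to_csv(outdir / "pca_loadings.csv")
        bundle.pca.scores.to_csv(outdir / "pca_scores.csv")
        pd.DataFrame({
            "eigenvalue": bundle.pca.eigenvalues,
            "proportion": bundle.pca.proportion,
        }).to_csv(outdir / "pca_eigenvalues.csv", index=False)
    _write_figures(bundle, outdir)


def _write_figures(bundle: ReportBundle, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = bundle.tables.get("cpp_retest")
    if df is not None and not df.empty:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        order = sorted(df["first_tube"].unique(),
                       key=lambda s: int(str(s).split("_")[1]))
        ax.boxplot([df.loc[df["first_tube"] == g, "second_pi"] for g in order],
                   tick_labels=[str(g) for g in order])
        ax.set_xlabel("first-session tube")
        ax.set_ylabel("second-session PI")
        fig.tight_layout()
        fig.savefig(outdir / "cpp_retest.png", dpi=120)
        plt.close(fig)

    if bundle.pca is not None:
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        load = bundle.pca.loadings
        for var in load.index:
            ax.annotate("", xy=(load.loc[var, "PC1"], load.loc[var, "PC2"]),
                        xytext=(0, 0), arrowprops={"arrowstyle": "->"})
            ax.text(load.loc[var, "PC1"], load.loc[var, "PC2"], str(var),
                    fontsize=7)
        ax.set_xlabel("PC1 loading")
        ax.set_ylabel("PC2 loading")
        ax.axhline(0, lw=0.5, color="grey")
        ax.axvline(0, lw=0.5, color="grey")
        fig.tight_layout()
        fig.savefig(outdir / "pca_biplot.png", dpi=120)
        plt.close(fig)
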