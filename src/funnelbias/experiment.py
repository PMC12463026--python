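"""Grid orchestration: simulation cells, detector evaluation, benchmarks.

The default grid crosses 4 published-study counts (15, 30, 50, 75), 4
suppression severities (0, 1/10, 1/5, 1/3), 2 heterogeneity levels
(tau^2 = 0, 1) and 2 selection scenarios (p-value, effect size), with 100
replicates per cell.  Severity-0 cells are generated once per (n, tau^2) —
selection is a no-op there, so the scenario labels collapse.

Three entry points:

* :func:`run_grid` — evaluate registered detectors (LLM or statistical) on
  every cell and score them with the confusion-matrix metric suite.
* :func:`benchmark_traditional` — run Egger's, Begg's, and trim-and-fill on
  every generated dataset (no detector queries) and report per-n type-I
  error and pooled power.
* :func:`summarize_boxplots` — box-and-whisker summaries of per-replicate
  consistency, faceted by study count and severity, with a tidy CSV of the
  quartiles.

Cells are independent units of work with per-cell RNG streams derived from
the root seed, so results do not depend on scheduling order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .asymmetry import Method, begg_test, egger_test, trim_and_fill
from .funnel import payload_for_llm
from .llm import (
    Detector,
    DetectorUnavailable,
    InputMode,
    build_prompt,
    decide_with_agreement,
)
from .metrics import ConfusionCounts, compute_metrics, replication_ci, score_decision
from .simulate import MetaAnalysisDataset, ScenarioConfig, Selection, generate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "iter_cells",
    "run_grid",
    "benchmark_traditional",
    "aggregate_cell_metrics",
    "margin_consistency",
    "summarize_boxplots",
    "run_case_study",
]

DEFAULT_N_LIST = (15, 30, 50, 75)
DEFAULT_SEVERITIES = (0.0, 1 / 10, 1 / 5, 1 / 3)
DEFAULT_TAU2_LIST = (0.0, 1.0)
DEFAULT_SCENARIOS = (Selection.P_VALUE, Selection.EFFECT_SIZE)


@dataclass(frozen=True)
class GridSpec:
    """Full factorial specification of the simulation grid."""

    n_list: tuple[int, ...] = DEFAULT_N_LIST
    severities: tuple[float, ...] = DEFAULT_SEVERITIES
    tau2_list: tuple[float, ...] = DEFAULT_TAU2_LIST
    scenarios: tuple[Selection, ...] = DEFAULT_SCENARIOS
    replicates: int = 100
    seed: int = 0
    mu: float = 0.0
    alpha: float = 0.05
    directional: bool = True
    detectors: tuple[str, ...] = ()
    input_modes: tuple[InputMode, ...] = (InputMode.VISUAL,)

    @classmethod
    def from_yaml(cls, path) -> "GridSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in (
            "n_list", "severities", "tau2_list", "replicates", "seed",
            "mu", "alpha", "directional", "detectors",
        ):
            if key in raw:
                v = raw[key]
                kwargs[key] = tuple(v) if isinstance(v, list) else v
        if "scenarios" in raw:
            kwargs["scenarios"] = tuple(Selection(s) for s in raw["scenarios"])
        if "input_modes" in raw:
            kwargs["input_modes"] = tuple(InputMode(m) for m in raw["input_modes"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        data = {
            "n_list": list(self.n_list),
            "severities": list(self.severities),
            "tau2_list": list(self.tau2_list),
            "scenarios": [s.value for s in self.scenarios],
            "replicates": self.replicates,
            "seed": self.seed,
            "mu": self.mu,
            "alpha": self.alpha,
            "directional": self.directional,
            "detectors": list(self.detectors),
            "input_modes": [m.value for m in self.input_modes],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def iter_cells(spec: GridSpec) -> list[ScenarioConfig]:
    """All scenario cells of the grid, with severity-0 cells collapsed.

    For severity 0, selection is a no-op, so a single NONE cell per
    (n, tau^2) stands in for both scenario labels.
    """
    cells = []
    for n in spec.n_list:
        for tau2 in spec.tau2_list:
            for sev in spec.severities:
                if sev == 0:
                    cells.append(
                        ScenarioConfig(
                            n_published=n, severity=0.0, tau2=tau2,
                            selection=Selection.NONE, mu=spec.mu,
                            alpha=spec.alpha, seed=spec.seed,
                            directional=spec.directional,
                        )
                    )
                else:
                    for scen in spec.scenarios:
                        cells.append(
                            ScenarioConfig(
                                n_published=n, severity=sev, tau2=tau2,
                                selection=scen, mu=spec.mu, alpha=spec.alpha,
                                seed=spec.seed, directional=spec.directional,
                            )
                        )
    return cells


def _cell_row(config: ScenarioConfig, dataset: MetaAnalysisDataset) -> dict:
    return {
        "cell_id": config.cell_key(),
        "n": config.n_published,
        "severity": config.severity,
        "tau2": config.tau2,
        "scenario": config.selection.value,
        "replicate": dataset.replicate_id,
        "regenerations": dataset.regeneration_count,
        "truth_present": config.pb_present,
    }


def run_grid(
    spec: GridSpec,
    detectors: dict[str, Detector],
    repeats: int = 5,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Evaluate every registered detector on every cell x replicate.

    Returns the decision log (one row per dataset x detector x input mode)
    and a list of (cell, detector) combinations left incomplete because a
    detector was unavailable.  Deterministic detectors are queried once;
    stochastic ones `repeats` times under the strict agreement rule.
    Funnel plots are rasterized only when some detector consumes images.
    """
    rows: list[dict] = []
    incomplete: list[str] = []
    need_image = any(d.needs_image for d in detectors.values())
    for config in iter_cells(spec):
        for rep in range(spec.replicates):
            dataset = generate_dataset(config, rep)
            payloads = {}
            for mode in spec.input_modes:
                payloads[mode] = payload_for_llm(
                    dataset,
                    include_data=(mode is InputMode.COMBINED),
                    include_image=need_image,
                )
            for name, det in detectors.items():
                for mode in spec.input_modes:
                    if getattr(det, "needs_data", False) and mode is not InputMode.COMBINED:
                        continue
                    bundle = build_prompt(mode, payloads[mode])
                    n_queries = 1 if det.deterministic else repeats
                    try:
                        decision = decide_with_agreement(det, bundle, n_queries)
                    except DetectorUnavailable as err:
                        logger.warning("detector %s unavailable: %s", name, err)
                        incomplete.append(f"{config.cell_key()}|{name}|{mode.value}")
                        continue
                    row = _cell_row(config, dataset)
                    row.update(
                        detector=name,
                        input_mode=mode.value,
                        verdict=decision.verdict.value,
                        score=score_decision(decision.verdict, config.pb_present),
                    )
                    rows.append(row)
    log = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        log.to_csv(out_dir / "decision_log.csv", index=False)
        aggregate_cell_metrics(log).to_csv(out_dir / "cell_metrics.csv", index=False)
    return log, incomplete


def aggregate_cell_metrics(log: pd.DataFrame) -> pd.DataFrame:
    """Metric suite per (detector, input mode, cell) from the decision log."""
    out = []
    keys = ["detector", "input_mode", "n", "severity", "tau2", "scenario"]
    for group, sub in log.groupby(keys):
        counts = ConfusionCounts()
        for cell in sub["score"]:
            counts.add(cell)
        ms = compute_metrics(counts)
        row = dict(zip(keys, group))
        row.update(ms.as_dict())
        row.update(tp=counts.tp, fp=counts.fp, tn=counts.tn, fn=counts.fn)
        out.append(row)
    return pd.DataFrame(out)


def margin_consistency(
    log: pd.DataFrame, by: Sequence[str] = ("detector", "input_mode", "n", "severity")
) -> pd.DataFrame:
    """Per-replicate consistency aggregated over the margins not in `by`.

    Each replicate contributes the fraction of its decisions (across the
    collapsed sub-cells) that were correct; the point estimate is the mean
    of those replicate values and the CI their percentile interval.
    """
    correct = log.assign(correct=log["score"].isin(["TP", "TN"]).astype(float))
    per_rep = (
        correct.groupby([*by, "replicate"])["correct"].mean().reset_index()
    )
    out = []
    for group, sub in per_rep.groupby(list(by)):
        vals = sub["correct"].to_numpy()
        lo, hi = replication_ci(vals) if vals.size >= 2 else (vals[0], vals[0])
        row = dict(zip(by, group))
        row.update(consistency=float(vals.mean()), ci_low=lo, ci_high=hi,
                   replicates=int(vals.size))
        out.append(row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Traditional-method benchmark


def benchmark_traditional(
    spec: GridSpec,
    trim_estimator: str = "L0",
    max_regenerations: int = 1000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the three classical tests on every dataset of the grid.

    Returns ``(report, flag_log)``.  The report gives, per study count n and
    per method plus a pooled row: the type-I error (rejection rate over
    severity-0 cells) and the power (rejection rate pooled over all
    bias-present cells, both scenarios, both tau^2 values, all severities).
    Trim-and-fill's default binary call is the parameter-free k0 > 0 rule of
    the L0 estimator; note that this rule is liberal under the null, so its
    "type-I error" column is expected to sit far above alpha.  Pass
    ``trim_estimator="R0"`` for the run-length estimator with its exact
    test, whose call does control type I.
    """
    rows = []
    for config in iter_cells(spec):
        for rep in range(spec.replicates):
            dataset = generate_dataset(config, rep, max_regenerations=max_regenerations)
            y, s = dataset.effects(), dataset.ses()
            results = {
                Method.EGGER: egger_test(y, s, alpha=spec.alpha),
                Method.BEGG: begg_test(y, s, alpha=spec.alpha),
                Method.TRIM_FILL: trim_and_fill(
                    y, s, estimator=trim_estimator, alpha=spec.alpha
                ),
            }
            base = _cell_row(config, dataset)
            for method, res in results.items():
                rows.append(
                    {
                        **base,
                        "method": method.value,
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "k0": res.k0,
                        "flagged": bool(res.flagged),
                    }
                )
    flag_log = pd.DataFrame(rows)

    report_rows = []
    for n, sub_n in flag_log.groupby("n"):
        null_mask = sub_n["severity"] == 0
        for method, sub_m in sub_n.groupby("method"):
            m_null = sub_m[sub_m["severity"] == 0]
            m_alt = sub_m[sub_m["severity"] > 0]
            report_rows.append(
                {
                    "n": n,
                    "method": method,
                    "type1": float(m_null["flagged"].mean()) if len(m_null) else np.nan,
                    "power": float(m_alt["flagged"].mean()) if len(m_alt) else np.nan,
                    "n_null": int(len(m_null)),
                    "n_alt": int(len(m_alt)),
                }
            )
        alt = sub_n[~null_mask]
        null = sub_n[null_mask]
        report_rows.append(
            {
                "n": n,
                "method": "pooled",
                "type1": float(null["flagged"].mean()) if len(null) else np.nan,
                "power": float(alt["flagged"].mean()) if len(alt) else np.nan,
                "n_null": int(len(null)),
                "n_alt": int(len(alt)),
            }
        )
    return pd.DataFrame(report_rows), flag_log


# ---------------------------------------------------------------------------
# Box-plot summaries


def _box_stats(values: np.ndarray) -> dict:
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "n_outliers": int(values.size - inside.size),
    }


def summarize_boxplots(
    per_replicate: pd.DataFrame,
    out_dir: str | Path,
    value_col: str = "correct",
    facet_col: str = "n",
    group_col: str = "severity",
) -> pd.DataFrame:
    """Box-and-whisker summaries of per-replicate consistency values.

    One subplot per `facet_col` level, one box per `group_col` level;
    boxes span Q1..Q3 with the median line, whiskers extend to the most
    extreme value within 1.5 IQR of the quartiles, outliers drawn as
    points.  A tidy CSV of the quartile statistics is written alongside the
    figure and returned.  Missing groups are drawn empty with a warning.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    facets = sorted(per_replicate[facet_col].unique())
    groups = sorted(per_replicate[group_col].unique())

    fig, axes = plt.subplots(
        1, len(facets), figsize=(4 * len(facets), 4), squeeze=False, sharey=True
    )
    stats_rows = []
    for ax, facet in zip(axes[0], facets):
        data, labels = [], []
        for g in groups:
            vals = per_replicate.loc[
                (per_replicate[facet_col] == facet) & (per_replicate[group_col] == g),
                value_col,
            ].to_numpy(dtype=float)
            labels.append(str(g))
            if vals.size == 0:
                logger.warning("no values for %s=%s, %s=%s", facet_col, facet,
                               group_col, g)
                data.append([])
                continue
            data.append(vals)
            stats_rows.append(
                {facet_col: facet, group_col: g, "n_values": vals.size,
                 **_box_stats(vals)}
            )
        ax.boxplot([d if len(d) else [np.nan] for d in data],
                   tick_labels=labels, whis=1.5)
        ax.set_title(f"{facet_col} = {facet}")
        ax.set_xlabel(group_col)
    axes[0][0].set_ylabel(value_col)
    fig.tight_layout()
    fig.savefig(out_dir / "consistency_boxplots.png", dpi=100)
    plt.close(fig)

    stats_df = pd.DataFrame(stats_rows)
    stats_df.to_csv(out_dir / "consistency_quartiles.csv", index=False)
    return stats_df


# ---------------------------------------------------------------------------
# Case study on user-supplied data


def run_case_study(effects, ses, alpha: float = 0.05) -> dict:
    """Run all three classical detectors plus a REML fit on a user table."""
    from .reml import reml_fit

    fit = reml_fit(effects, ses)
    return {
        "reml": fit,
        "egger": egger_test(effects, ses, alpha=alpha),
        "begg": begg_test(effects, ses, alpha=alpha),
        "trim_fill_L0": trim_and_fill(effects, ses, estimator="L0", alpha=alpha),
        "trim_fill_R0": trim_and_fill(effects, ses, estimator="R0", alpha=alpha),
    }
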