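"""Synthetic meta-analysis generator with controlled selective non-publication.

Study-level data follow the hierarchical two-stage normal model used in
simulation studies of publication bias: each study i has a true effect
``mu_i ~ Normal(mu, tau2)`` and an observed effect
``y_i ~ Normal(mu_i, s_i^2)`` with within-study standard error
``s_i ~ Uniform(1, 4)``.  Publication bias is induced by ranking a pool of
``n + m`` studies by how "unfavorable" they are and deleting the worst ``m``,
leaving ``n`` published studies; the deleted studies are retained for audit.

Two selection mechanisms are provided:

* ``P_VALUE`` — suppression driven by statistical significance.  By default
  the ranking is directional (one-sided p-value, so the most negative /
  least significant results are dropped); ``directional=False`` ranks by the
  two-sided p-value instead, which suppresses symmetrically in sign.
* ``EFFECT_SIZE`` — suppression driven by the estimated effect.  By default
  the algebraically smallest effects are dropped; ``directional=False``
  drops the smallest absolute effects.

Severity is the ratio m/n of suppressed to published studies (0, 1/10, 1/5,
1/3 on the default grid), with m rounded half-up.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Selection",
    "StudyRecord",
    "ScenarioConfig",
    "MetaAnalysisDataset",
    "SimulationFailure",
    "round_half_up",
    "cell_rng",
    "simulate_study_pool",
    "apply_selection",
    "generate_dataset",
    "dataset_to_json_table",
    "write_dataset_csv",
    "read_dataset_csv",
    "read_study_table",
]

SE_LOW = 1.0
SE_HIGH = 4.0


class Selection(str, Enum):
    """How the suppressed studies are chosen."""

    NONE = "none"
    P_VALUE = "p_value"
    EFFECT_SIZE = "effect_size"


class SimulationFailure(RuntimeError):
    """Raised when a scenario cell cannot produce a convergent dataset."""


def round_half_up(x: float) -> int:
    """Round to the nearest integer with .5 rounded away from zero (x >= 0)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class StudyRecord:
    """One study: effect estimate y, standard error s, two-sided p-value."""

    effect: float
    se: float
    p_two_sided: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValueError(f"standard error must be positive, got {self.se}")
        if self.p_two_sided is None:
            object.__setattr__(
                self, "p_two_sided", two_sided_p(self.effect, self.se)
            )

    @property
    def z(self) -> float:
        return self.effect / self.se

    @property
    def p_one_sided(self) -> float:
        """Upper-tail p; large when the result is negative or null-ish."""
        return float(stats.norm.sf(self.z))


def two_sided_p(effect: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(effect / se)))


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation cell of the evaluation grid.

    Parameters
    ----------
    n_published:
        Number of published studies n (the funnel-plot studies).
    severity:
        m/n, the ratio of suppressed to published studies.
    tau2:
        Between-study variance tau^2 of the true effects.
    selection:
        Suppression mechanism; must be NONE exactly when severity == 0.
    mu:
        True overall effect (0 on the default grid).
    alpha:
        Two-sided significance level defining "significant" (0.05).
    seed:
        Root seed; per-replicate streams are derived from it.
    directional:
        If True (default) suppression is one-sided (least favorable results
        removed); if False it is symmetric in sign (largest two-sided p /
        smallest |effect| removed).
    floor_m:
        If True, m = floor(severity * n) instead of round-half-up.
    """

    n_published: int
    severity: float = 0.0
    tau2: float = 0.0
    selection: Selection = Selection.NONE
    mu: float = 0.0
    alpha: float = 0.05
    seed: int = 0
    directional: bool = True
    floor_m: bool = False

    def __post_init__(self) -> None:
        if self.n_published < 2:
            raise ValueError("n_published must be >= 2")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if not 0 <= self.severity < 1:
            raise ValueError("severity must be in [0, 1)")
        if (self.severity == 0) != (self.selection is Selection.NONE):
            raise ValueError(
                "severity == 0 exactly when selection is NONE "
                f"(got severity={self.severity}, selection={self.selection})"
            )

    @property
    def m_removed(self) -> int:
        if self.severity == 0:
            return 0
        raw = self.severity * self.n_published
        m = int(math.floor(raw)) if self.floor_m else round_half_up(raw)
        return max(m, 1)

    @property
    def pb_present(self) -> bool:
        """Ground-truth label used for scoring."""
        return self.severity > 0

    def cell_key(self) -> str:
        """Stable identifier of the cell (excludes seed and replicate)."""
        return (
            f"n{self.n_published}-sev{self.severity:.6f}-tau{self.tau2:.6f}"
            f"-{self.selection.value}-mu{self.mu:.6f}"
            f"-{'dir' if self.directional else 'sym'}"
        )


@dataclass
class MetaAnalysisDataset:
    """A generated meta-analysis: published studies plus the audit trail."""

    published: tuple[StudyRecord, ...]
    unpublished: tuple[StudyRecord, ...]
    config: ScenarioConfig
    replicate_id: int
    regeneration_count: int = 0
    fit: object | None = None  # REMLFit of the published studies

    def __post_init__(self) -> None:
        if len(self.published) != self.config.n_published:
            raise ValueError(
                f"expected {self.config.n_published} published studies, "
                f"got {len(self.published)}"
            )

    @property
    def pb_present(self) -> bool:
        return self.config.pb_present

    @property
    def dataset_id(self) -> str:
        return f"{self.config.cell_key()}-rep{self.replicate_id}"

    @property
    def opaque_ref(self) -> str:
        """Detector-facing identifier that reveals nothing about the cell."""
        return hashlib.blake2b(self.dataset_id.encode(), digest_size=8).hexdigest()

    def effects(self) -> np.ndarray:
        return np.array([s.effect for s in self.published])

    def ses(self) -> np.ndarray:
        return np.array([s.se for s in self.published])


def cell_rng(root_seed: int, cell_key: str, replicate_id: int) -> np.random.Generator:
    """Independent, reproducible stream for one (cell, replicate).

    The stream seed is a 64-bit hash of (root seed, cell key, replicate), so
    any cell/replicate can be regenerated in isolation and scheduling order
    cannot change results.
    """
    token = f"{root_seed}|{cell_key}|{replicate_id}".encode()
    digest = hashlib.blake2b(token, digest_size=8).digest()
    return np.random.default_rng(int.from_bytes(digest, "big"))


def simulate_study_pool(
    total: int, mu: float, tau2: float, rng: np.random.Generator
) -> list[StudyRecord]:
    """Draw `total` independent studies from the two-stage normal model."""
    if total < 2:
        raise ValueError("need at least 2 studies")
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    ses = rng.uniform(SE_LOW, SE_HIGH, size=total)
    mu_i = rng.normal(mu, math.sqrt(tau2), size=total) if tau2 > 0 else np.full(total, mu)
    effects = rng.normal(mu_i, ses)
    return [StudyRecord(float(y), float(s)) for y, s in zip(effects, ses)]


def _suppression_key(record: StudyRecord, selection: Selection, directional: bool) -> float:
    # Larger key == less favorable == suppressed first.
    if selection is Selection.P_VALUE:
        return record.p_one_sided if directional else record.p_two_sided
    if selection is Selection.EFFECT_SIZE:
        return -record.effect if directional else -abs(record.effect)
    raise ValueError(f"no suppression key for selection={selection}")


def apply_selection(
    pool: Sequence[StudyRecord],
    selection: Selection,
    m_removed: int,
    directional: bool = True,
) -> tuple[list[StudyRecord], list[StudyRecord]]:
    """Split a study pool into (published, unpublished).

    The ``m_removed`` least favorable studies are moved to the unpublished
    list; survivors keep their generation order.  Ties are broken on
    (|effect| ascending, generation index), making the split deterministic.
    """
    if not 0 <= m_removed < len(pool):
        raise ValueError(f"m_removed must be in [0, {len(pool) - 1}], got {m_removed}")
    if m_removed == 0 or selection is Selection.NONE:
        if m_removed > 0:
            raise ValueError("selection NONE cannot remove studies")
        return list(pool), []
    order = sorted(
        range(len(pool)),
        key=lambda i: (
            -_suppression_key(pool[i], selection, directional),
            abs(pool[i].effect),
            i,
        ),
    )
    dropped = set(order[:m_removed])
    published = [r for i, r in enumerate(pool) if i not in dropped]
    unpublished = [pool[i] for i in sorted(dropped)]
    return published, unpublished


def generate_dataset(
    config: ScenarioConfig,
    replicate_id: int,
    fit_checker: Callable[["MetaAnalysisDataset"], object] | None = None,
    max_regenerations: int = 1000,
) -> MetaAnalysisDataset:
    """Generate one meta-analysis for a scenario cell.

    A pool of n + m studies is drawn, the selection mechanism removes m, and
    the published set is fitted by REML.  If Fisher scoring fails to
    converge the draw is discarded and regenerated (the count is recorded),
    so every returned dataset carries a convergent fit.
    """
    if fit_checker is None:
        from .reml import reml_fit

        def fit_checker(ds: MetaAnalysisDataset):
            return reml_fit(ds.effects(), ds.ses())

    rng = cell_rng(config.seed, config.cell_key(), replicate_id)
    m = config.m_removed
    for attempt in range(max_regenerations + 1):
        pool = simulate_study_pool(
            config.n_published + m, config.mu, config.tau2, rng
        )
        published, unpublished = apply_selection(
            pool, config.selection, m, config.directional
        )
        dataset = MetaAnalysisDataset(
            published=tuple(published),
            unpublished=tuple(unpublished),
            config=config,
            replicate_id=replicate_id,
            regeneration_count=attempt,
        )
        fit = fit_checker(dataset)
        if getattr(fit, "converged", True):
            dataset.fit = fit
            return dataset
    raise SimulationFailure(
        f"no convergent fit after {max_regenerations} regenerations in cell "
        f"{config.cell_key()} replicate {replicate_id}"
    )


# ---------------------------------------------------------------------------
# External formats: CSV audit table and the JSON study table sent to detectors


def dataset_to_json_table(dataset: MetaAnalysisDataset) -> str:
    """JSON study-level table of the *published* studies only."""
    payload = {
        "studies": [
            {"effect_size": s.effect, "standard_error": s.se}
            for s in dataset.published
        ]
    }
    return json.dumps(payload)


def _to_frame(dataset: MetaAnalysisDataset) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(dataset.published):
        rows.append({"study_id": i, "effect": s.effect, "se": s.se, "published": 1})
    off = len(dataset.published)
    for j, s in enumerate(dataset.unpublished):
        rows.append({"study_id": off + j, "effect": s.effect, "se": s.se, "published": 0})
    return pd.DataFrame(rows, columns=["study_id", "effect", "se", "published"])


def write_dataset_csv(dataset: MetaAnalysisDataset, path) -> None:
    _to_frame(dataset).to_csv(path, index=False)


def read_dataset_csv(path) -> tuple[list[StudyRecord], list[StudyRecord]]:
    """Read a dataset CSV back into (published, unpublished) records."""
    df = pd.read_csv(path)
    pub = [
        StudyRecord(float(r.effect), float(r.se))
        for r in df[df["published"] == 1].itertuples()
    ]
    unpub = [
        StudyRecord(float(r.effect), float(r.se))
        for r in df[df["published"] == 0].itertuples()
    ]
    return pub, unpub


def read_study_table(path) -> list[StudyRecord]:
    """Read a user study table (CSV with effect/se columns, or the JSON twin)."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            data = json.load(fh)
        return [
            StudyRecord(float(s["effect_size"]), float(s["standard_error"]))
            for s in data["studies"]
        ]
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    eff = cols.get("effect", cols.get("effect_size", cols.get("yi")))
    se = cols.get("se", cols.get("standard_error", cols.get("sei")))
    if eff is None or se is None:
        raise ValueError("study table needs effect/effect_size and se/standard_error columns")
    return [StudyRecord(float(y), float(s)) for y, s in zip(df[eff], df[se])]
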