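"""Funnel-plot rendering and detector-facing payload packaging.

Funnel plots are drawn in a minimal canonical style — effect size on the
x-axis, standard error on an inverted y-axis (most precise studies at the
top), a vertical reference line at the REML pooled estimate, optional 95%
pseudo-confidence wedge — and rasterized to an exactly 600 x 600 pixel PNG.
Rendering is deterministic: the same dataset and style yield byte-identical
PNG output, which the evaluation harness relies on for reproducibility.

Payloads sent to detectors contain only the base64 image and (optionally)
the JSON study table; ground-truth labels and the suppressed studies are
unreachable from them by construction.
"""

from __future__ import annotations

import base64
import io
from dataclasses import dataclass

import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .simulate import MetaAnalysisDataset

__all__ = ["FunnelImage", "funnel_points", "pseudo_ci_bounds", "render_funnel", "payload_for_llm"]

_SIZE_PX = 600
_DPI = 100


@dataclass(frozen=True)
class FunnelImage:
    """A rendered funnel plot: PNG bytes, base64 text, source dataset id."""

    png_bytes: bytes
    base64: str
    dataset_ref: str

    @property
    def size(self) -> tuple[int, int]:
        """(width, height) parsed from the PNG IHDR chunk."""
        w = int.from_bytes(self.png_bytes[16:20], "big")
        h = int.from_bytes(self.png_bytes[20:24], "big")
        return w, h


def funnel_points(dataset: MetaAnalysisDataset) -> tuple[np.ndarray, np.ndarray]:
    """Plotted coordinates: (effects, standard errors) of published studies."""
    return dataset.effects(), dataset.ses()


def _pooled_estimate(dataset: MetaAnalysisDataset) -> float:
    if dataset.fit is not None:
        return float(dataset.fit.mu_hat)
    from .reml import reml_fit

    return float(reml_fit(dataset.effects(), dataset.ses()).mu_hat)


def pseudo_ci_bounds(mu_hat: float, se_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """95% pseudo-confidence region: mu_hat +/- 1.96 * se, symmetric exactly."""
    half = 1.96 * se_grid
    return mu_hat - half, mu_hat + half


def render_funnel(dataset: MetaAnalysisDataset, pseudo_ci: bool = False) -> FunnelImage:
    """Render the published studies as a 600 x 600 px funnel-plot PNG."""
    if len(dataset.published) < 2:
        raise ValueError("need at least 2 published studies to render a funnel plot")
    effects, ses = funnel_points(dataset)
    mu_hat = _pooled_estimate(dataset)

    fig = Figure(figsize=(_SIZE_PX / _DPI, _SIZE_PX / _DPI), dpi=_DPI, facecolor="white")
    canvas = FigureCanvasAgg(fig)
    ax = fig.add_subplot(111, facecolor="white")

    y_max = float(ses.max()) * 1.05
    if pseudo_ci:
        se_grid = np.linspace(0.0, y_max, 50)
        lo, hi = pseudo_ci_bounds(mu_hat, se_grid)
        ax.plot(lo, se_grid, linestyle="--", color="0.6", linewidth=1.0)
        ax.plot(hi, se_grid, linestyle="--", color="0.6", linewidth=1.0)
    ax.axvline(mu_hat, color="0.3", linewidth=1.0)
    ax.scatter(effects, ses, s=28, facecolors="none", edgecolors="black", linewidths=1.0)

    half_span = float(np.max(np.abs(effects - mu_hat))) * 1.05
    half_span = max(half_span, 1e-6)
    ax.set_xlim(mu_hat - half_span, mu_hat + half_span)
    ax.set_ylim(y_max, 0.0)  # inverted: smallest se at the top
    ax.set_xlabel("Effect size")
    ax.set_ylabel("Standard error")

    buf = io.BytesIO()
    canvas.print_png(buf)
    png = buf.getvalue()
    return FunnelImage(
        png_bytes=png,
        base64=base64.b64encode(png).decode("ascii"),
        dataset_ref=dataset.opaque_ref,
    )


def payload_for_llm(
    dataset: MetaAnalysisDataset,
    include_data: bool,
    include_image: bool = True,
    pseudo_ci: bool = False,
) -> dict:
    """Build the request payload a detector receives for one meta-analysis.

    The payload carries the base64 funnel image and, when ``include_data``,
    the study-level table (effect sizes and standard errors) — never the
    ground-truth label, the severity, or the suppressed studies.
    ``include_image=False`` skips rasterization for detectors that consume
    only the numeric table.
    """
    payload: dict = {"dataset_ref": dataset.opaque_ref}
    if include_image:
        image = render_funnel(dataset, pseudo_ci=pseudo_ci)
        payload["image_base64"] = image.base64
        payload["image_media_type"] = "image/png"
    if include_data:
        payload["studies"] = [
            {"effect_size": s.effect, "standard_error": s.se}
            for s in dataset.published
        ]
    return payload
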