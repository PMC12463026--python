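"""Detector interface: prompt construction, response parsing, agreement rule.

Any publication-bias detector — a multimodal chat model behind an HTTP API,
or a deterministic statistical test wrapped to speak the same protocol —
implements a single method, ``query(bundle) -> str``.  Stochastic detectors
are queried five times per funnel plot and a verdict is recorded only when
all five parsed answers are exactly identical; anything else is
INCONSISTENT (or UNPARSEABLE when no run could be parsed).  Raw transcripts
are kept verbatim for audit.

Scoring note: non-verdicts (INCONSISTENT / UNPARSEABLE) count as incorrect
for the true label downstream — a false negative when bias is present and a
false positive when it is absent — because a strict-agreement rule treats
anything short of unanimous agreement as a failed identification.  This
choice shapes every metric and is applied uniformly.
"""

from __future__ import annotations

import json
import re
import time
import urllib.request
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Protocol, Sequence

__all__ = [
    "Verdict",
    "PromptBundle",
    "DetectorDecision",
    "DetectorUnavailable",
    "Detector",
    "build_prompt",
    "parse_response",
    "decide_with_agreement",
    "AlwaysPresentDetector",
    "AlwaysAbsentDetector",
    "ScriptedDetector",
    "OracleDetector",
    "EggerDetector",
    "ChatCompletionsDetector",
    "DETECTOR_REGISTRY",
    "make_detector",
]


class Verdict(str, Enum):
    PRESENT = "present"
    ABSENT = "absent"
    INCONSISTENT = "inconsistent"
    UNPARSEABLE = "unparseable"


class InputMode(str, Enum):
    VISUAL = "visual"
    COMBINED = "combined"


# Contextual prompt blocks given to multimodal detectors.  The summary
# explains what a funnel plot shows; the criteria spell out how to judge it;
# the combined-input suffix tells the model to cross-check the plot against
# the numeric study table.
SUMMARY_TEXT = (
    "A funnel plot is commonly used to assess publication bias in "
    "meta-analyses. Each point on the funnel plot represents an individual "
    "study. The vertical axis (y-axis) shows a measure of precision (e.g., "
    "standard error), and the horizontal axis (x-axis) indicates the effect "
    "size. In the absence of publication bias, the funnel plot should "
    "resemble a symmetric inverted triangle. Asymmetry in the funnel plot "
    "may suggest publication bias."
)

CRITERIA_TEXT = (
    "Criteria to make the decision based on plots:\n"
    "1. Symmetry around the overall effect size - look for symmetry "
    "(minimal or no bias) or asymmetry with visible gaps (potential bias).\n"
    "2. Distribution of studies by precision - check if high-precision "
    "studies cluster around the mean effect size, and if low-precision "
    "studies are scattered symmetrically (balanced distribution = no bias, "
    "skewed clustering = potential bias).\n"
    "3. Effect size trends - identify if smaller studies show larger "
    "effects (no systematic change = minimal/no bias, clear trend = "
    "potential bias).\n"
    "4. Missing study patterns - look for gaps in expected regions, "
    "indicating selective publication (no gap = no bias, noticeable gaps = "
    "potential bias)."
)

COMBINED_SUFFIX = (
    "Assess the symmetry of the funnel plot by examining the relationship "
    "between effect sizes and standard errors, where each point represents "
    "a trial. Supplement visual input with numerical input by analyzing the "
    "underlying data, including the distribution of effect sizes across "
    "different standard error levels, to provide a comprehensive evaluation "
    "of publication bias."
)

ANSWER_INSTRUCTION = (
    'The output is Present/Absent of PB. Answer with exactly one word: '
    '"Present" or "Absent".'
)


@dataclass(frozen=True)
class PromptBundle:
    """Everything one detector query needs: prompt text plus the payload."""

    context_text: str
    criteria_text: str
    combined_suffix: str | None
    payload: dict

    @property
    def full_text(self) -> str:
        parts = [self.context_text, self.criteria_text]
        if self.combined_suffix:
            parts.append(self.combined_suffix)
        parts.append(ANSWER_INSTRUCTION)
        return "\n\n".join(parts)


@dataclass
class DetectorDecision:
    """Final verdict for one dataset, with the raw transcripts for audit."""

    verdict: Verdict
    runs: tuple[str, ...]
    detector_id: str
    parsed: tuple[Verdict, ...] = field(default=())


class DetectorUnavailable(RuntimeError):
    """Transport failed after retries; carries any partial transcripts."""

    def __init__(self, message: str, transcripts: Sequence[str] = ()):  # noqa: D107
        super().__init__(message)
        self.transcripts = tuple(transcripts)


class Detector(Protocol):
    detector_id: str
    deterministic: bool
    needs_image: bool

    def query(self, bundle: PromptBundle) -> str: ...


def build_prompt(mode: InputMode | str, payload: dict) -> PromptBundle:
    """Assemble the contextual prompt for the given input mode.

    VISUAL uses the funnel-plot summary plus the four decision criteria;
    COMBINED appends the data-table instruction and requires the payload to
    carry the study table (and vice versa).
    """
    mode = InputMode(mode)
    has_data = "studies" in payload
    if mode is InputMode.COMBINED and not has_data:
        raise ValueError("COMBINED mode requires a payload with the study table")
    if mode is InputMode.VISUAL and has_data:
        raise ValueError("VISUAL mode payload must not carry the study table")
    return PromptBundle(
        context_text=SUMMARY_TEXT,
        criteria_text=CRITERIA_TEXT,
        combined_suffix=COMBINED_SUFFIX if mode is InputMode.COMBINED else None,
        payload=payload,
    )


_PRESENT_RE = re.compile(r"\bpresent\b", re.IGNORECASE)
_ABSENT_RE = re.compile(r"\babsent\b", re.IGNORECASE)
_NEGATED_RE = re.compile(
    r"\b(?:no|without|absence\s+of)\s+(?:evidence\s+of\s+)?"
    r"(?:publication\s+bias|pb|bias)\b",
    re.IGNORECASE,
)


def parse_response(text: str) -> Verdict:
    """Map a free-text answer onto Present/Absent, or UNPARSEABLE.

    Word-boundary matching of the two answer tokens, with the common
    negated phrasing ("no publication bias") read as Absent.  A text
    carrying both signals, or neither, is UNPARSEABLE.
    """
    signals = set()
    if _PRESENT_RE.search(text):
        signals.add(Verdict.PRESENT)
    if _ABSENT_RE.search(text) or _NEGATED_RE.search(text):
        signals.add(Verdict.ABSENT)
    if len(signals) == 1:
        return signals.pop()
    return Verdict.UNPARSEABLE


def decide_with_agreement(
    detector: Detector, bundle: PromptBundle, repeats: int = 5
) -> DetectorDecision:
    """Query a detector `repeats` times and apply the strict agreement rule.

    A PRESENT/ABSENT verdict is recorded only when every parsed run is
    identical and parseable; all-unparseable runs yield UNPARSEABLE and any
    other disagreement yields INCONSISTENT.  Deterministic detectors are
    typically queried once (``repeats=1``).
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    runs = tuple(detector.query(bundle) for _ in range(repeats))
    parsed = tuple(parse_response(r) for r in runs)
    distinct = set(parsed)
    if distinct == {Verdict.UNPARSEABLE}:
        verdict = Verdict.UNPARSEABLE
    elif len(distinct) == 1:
        verdict = parsed[0]
    else:
        verdict = Verdict.INCONSISTENT
    return DetectorDecision(
        verdict=verdict, runs=runs, detector_id=detector.detector_id, parsed=parsed
    )


# ---------------------------------------------------------------------------
# Concrete detectors


class AlwaysPresentDetector:
    """Constant detector: answers "Present" unconditionally."""

    detector_id = "always-present"
    deterministic = True
    needs_image = False

    def query(self, bundle: PromptBundle) -> str:
        return "Present"


class AlwaysAbsentDetector:
    detector_id = "always-absent"
    deterministic = True
    needs_image = False

    def query(self, bundle: PromptBundle) -> str:
        return "Absent"


class ScriptedDetector:
    """Replays a fixed sequence of responses (cycling); for tests and demos."""

    deterministic = True
    needs_image = False

    def __init__(self, responses: Sequence[str], detector_id: str = "scripted"):
        if not responses:
            raise ValueError("need at least one scripted response")
        self.responses = list(responses)
        self.detector_id = detector_id
        self._i = 0

    def query(self, bundle: PromptBundle) -> str:
        r = self.responses[self._i % len(self.responses)]
        self._i += 1
        return r


class OracleDetector:
    """Answers from the ground truth via an out-of-band lookup.

    Test-only upper bound: the truth is supplied by the harness through a
    ``dataset_ref -> bool`` lookup, never through the payload, so the
    leakage guarantee on detector-facing objects still holds.
    """

    detector_id = "oracle"
    deterministic = True
    needs_image = False

    def __init__(self, truth_lookup: Callable[[str], bool]):
        self.truth_lookup = truth_lookup

    def query(self, bundle: PromptBundle) -> str:
        return "Present" if self.truth_lookup(bundle.payload["dataset_ref"]) else "Absent"


class EggerDetector:
    """Deterministic detector backed by Egger's regression test.

    Reads the study table from the payload (COMBINED mode required) and
    answers Present when the intercept test rejects at ``alpha``.
    """

    deterministic = True
    needs_image = False
    needs_data = True  # only operable in COMBINED mode

    def __init__(self, alpha: float = 0.05, detector_id: str = "egger"):
        self.alpha = alpha
        self.detector_id = detector_id

    def query(self, bundle: PromptBundle) -> str:
        studies = bundle.payload.get("studies")
        if not studies:
            raise ValueError("egger detector needs the study table (COMBINED mode)")
        from .asymmetry import egger_test

        effects = [s["effect_size"] for s in studies]
        ses = [s["standard_error"] for s in studies]
        return "Present" if egger_test(effects, ses, alpha=self.alpha).flagged else "Absent"


def _urllib_transport(url: str, headers: dict, body: dict, timeout: float) -> dict:
    req = urllib.request.Request(
        url, data=json.dumps(body).encode(), headers=headers, method="POST"
    )
    with urllib.request.urlopen(req, timeout=timeout) as resp:
        return json.loads(resp.read().decode())


class ChatCompletionsDetector:
    """Multimodal chat-API detector (chat-completions contract).

    Each query POSTs one message containing the prompt text and exactly one
    embedded base64 PNG; requests are independent and stateless.  Transport
    failures are retried with exponential backoff (3 attempts) before
    raising :class:`DetectorUnavailable`.  The transport is injectable so
    the client can be exercised without a network.
    """

    deterministic = False
    needs_image = True

    def __init__(
        self,
        endpoint: str,
        model: str,
        api_key: str | None = None,
        temperature: float | None = None,
        timeout: float = 60.0,
        max_attempts: int = 3,
        transport: Callable[[str, dict, dict, float], dict] | None = None,
        detector_id: str | None = None,
    ):
        self.endpoint = endpoint
        self.model = model
        self.api_key = api_key
        self.temperature = temperature
        self.timeout = timeout
        self.max_attempts = max_attempts
        self.transport = transport or _urllib_transport
        self.detector_id = detector_id or f"chat:{model}"

    def _request_body(self, bundle: PromptBundle) -> dict:
        content: list[dict] = [{"type": "text", "text": bundle.full_text}]
        content.append(
            {
                "type": "image_url",
                "image_url": {
                    "url": "data:image/png;base64," + bundle.payload["image_base64"]
                },
            }
        )
        if "studies" in bundle.payload:
            content.append(
                {
                    "type": "text",
                    "text": "Study-level data table (JSON):\n"
                    + json.dumps({"studies": bundle.payload["studies"]}),
                }
            )
        body = {"model": self.model, "messages": [{"role": "user", "content": content}]}
        if self.temperature is not None:
            body["temperature"] = self.temperature
        return body

    def query(self, bundle: PromptBundle) -> str:
        if "image_base64" not in bundle.payload:
            raise ValueError("chat detector requires an image payload")
        headers = {"Content-Type": "application/json"}
        if self.api_key:
            headers["Authorization"] = f"Bearer {self.api_key}"
        body = self._request_body(bundle)
        last_err: Exception | None = None
        for attempt in range(self.max_attempts):
            try:
                resp = self.transport(self.endpoint, headers, body, self.timeout)
                return resp["choices"][0]["message"]["content"]
            except Exception as err:  # noqa: BLE001 — transport errors are retried
                last_err = err
                if attempt < self.max_attempts - 1:
                    time.sleep(2.0**attempt * 0.1)
        raise DetectorUnavailable(f"detector {self.detector_id}: {last_err}")


DETECTOR_REGISTRY: dict[str, Callable[..., Detector]] = {
    "always-present": AlwaysPresentDetector,
    "always-absent": AlwaysAbsentDetector,
    "egger": EggerDetector,
    "chat": ChatCompletionsDetector,
}


def make_detector(name: str, **kwargs) -> Detector:
    """Instantiate a registered detector by name."""
    if name not in DETECTOR_REGISTRY:
        raise KeyError(f"unknown detector {name!r}; known: {sorted(DETECTOR_REGISTRY)}")
    return DETECTOR_REGISTRY[name](**kwargs)
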