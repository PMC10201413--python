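"""Retention of an unnatural base pair from four-channel Sanger trace data.

A TPT3-NaM pair has no matching dye terminator, so Sanger signal terminates at
the pair: the ratio of mean signal after the site (R) to mean signal before it
(L), normalised against a natural-template control, is the read-through
(natural) fraction, and retention is ``F = 1 - normalized R/L``.  A second,
calibrated estimator mixes fully bridge-converted product with natural
template at known fractions, regresses the site C-channel response on the
mixture fraction, and inverts the line to read the converted fraction of an
unknown sample (classical calibration).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class RetentionMethod(enum.Enum):
    SIGNAL_ATTENUATION = "signal_attenuation"
    STANDARD_CURVE = "standard_curve"


@dataclass
class ChromatogramTrace:
    """Per-position four-channel intensities plus primary/secondary calls.

    ``channels`` is an (L, 4) float array ordered A, C, G, T.  The primary
    call is the argmax channel (alphabetical tie-break, flagged); a secondary
    call is recorded when the runner-up channel reaches ``secondary_threshold``
    of the primary.
    """

    channels: np.ndarray
    name: str = "trace"
    secondary_threshold: float = 0.2
    primary: list = field(init=False)
    secondary: list = field(init=False)
    ties: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[1] != 4:
            raise ValueError("channels must be an (L, 4) array ordered A,C,G,T")
        if (self.channels < 0).any():
            raise ValueError("intensities must be non-negative")
        self._recall()

    def _recall(self) -> None:
        best = self.channels.max(axis=1)
        # np.argmax returns the first maximum: alphabetical tie-break by channel order
        top = np.argmax(self.channels, axis=1)
        self.ties = (self.channels == best[:, None]).sum(axis=1) > 1
        self.primary = [BASES[i] for i in top]
        sec_calls = []
        for i, p in enumerate(top):
            row = self.channels[i]
            runners = [j for j in np.argsort(row)[::-1] if j != p]
            j = runners[0]
            if row[p] > 0 and row[j] >= self.secondary_threshold * row[p]:
                sec_calls.append(BASES[j])
            else:
                sec_calls.append(None)
        self.secondary = sec_calls

    def __len__(self) -> int:
        return len(self.channels)

    def channel(self, base: str) -> np.ndarray:
        return self.channels[:, _BASE_INDEX[base]]

    def intensity(self, position: int, base: str) -> float:
        """Channel intensity at a 0-based position."""
        return float(self.channels[position, _BASE_INDEX[base]])

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with 1-based positions (Sanger display convention)."""
        df = pd.DataFrame(self.channels, columns=list(BASES))
        df.insert(0, "pos", np.arange(1, len(self) + 1))
        df["call"] = self.primary
        df["secondary_call"] = [s if s is not None else "" for s in self.secondary]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str = "trace") -> "ChromatogramTrace":
        return cls(df[list(BASES)].to_numpy(dtype=float), name=name)


@dataclass(frozen=True)
class RetentionEstimate:
    site: int  # 0-based
    L: float
    R: float
    ratio: float
    F: float
    method: RetentionMethod
    sample: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.F <= 1.0:
            raise ValueError("retention F must lie in [0, 1]")


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of the normalised site C-channel response on mixture fraction."""

    fractions: tuple
    responses: tuple
    slope: float
    intercept: float
    r_squared: float
    reference_signal: float  # the 100% sample's C signal (L')
    site: int = 0


def _check_window(window: tuple, length: int) -> tuple:
    lo, hi = window
    if lo > hi:
        raise ValueError(f"empty window {window}")
    if lo < 1 or hi > length:
        raise ValueError(f"window {window} outside trace bounds 1..{length}")
    return lo, hi


def channel_window_mean(trace: ChromatogramTrace, channels="all", window=(35, 45)) -> float:
    """Mean intensity of the selected channels over a 1-based inclusive window.

    ``channels='all'`` averages the four channels jointly — the definition of
    the pre-/post-site signal levels L and R.
    """
    lo, hi = _check_window(window, len(trace))
    block = trace.channels[lo - 1 : hi]
    if channels == "all":
        return float(block.mean())
    idx = [_BASE_INDEX[b] for b in channels]
    return float(block[:, idx].mean())


def retention_signal_attenuation(
    trace: ChromatogramTrace,
    site: int,
    pre_window=(35, 45),
    post_window=(100, 110),
    control_trace: ChromatogramTrace | None = None,
) -> RetentionEstimate:
    """Retention by signal attenuation: ``F = 1 - clamp(normalised R/L, 0, 1)``.

    ``site`` is 0-based; the windows are 1-based inclusive and must lie
    strictly before and after the site.  When a natural-template control trace
    is supplied the R/L ratio is divided by the control's R/L; otherwise the
    normalisation factor is 1 (with a warning).
    """
    if pre_window[1] - 1 >= site:
        raise ValueError("pre_window must lie strictly before the site")
    if post_window[0] - 1 <= site:
        raise ValueError("post_window must lie strictly after the site")
    L = channel_window_mean(trace, "all", pre_window)
    R = channel_window_mean(trace, "all", post_window)
    if L <= 0:
        raise ValueError("no upstream signal (L = 0); cannot report retention")
    ratio = R / L
    if control_trace is not None:
        Lc = channel_window_mean(control_trace, "all", pre_window)
        Rc = channel_window_mean(control_trace, "all", post_window)
        if Lc <= 0 or Rc <= 0:
            raise ValueError("control trace has no signal in the chosen windows")
        ratio /= Rc / Lc
    else:
        warnings.warn("no control trace supplied; normalisation factor 1", stacklevel=2)
    if ratio > 1.0:
        warnings.warn(f"normalised R/L ratio {ratio:.3f} > 1 clamped to 1", stacklevel=2)
    clamped = min(max(ratio, 0.0), 1.0)
    return RetentionEstimate(
        site=site, L=L, R=R, ratio=clamped, F=1.0 - clamped,
        method=RetentionMethod.SIGNAL_ATTENUATION, sample=trace.name,
    )


def _site_response(trace: ChromatogramTrace, site: int) -> float:
    return trace.intensity(site, "C")


def build_standard_curve(labeled_traces, site: int) -> StandardCurve:
    """Fit the mixture standard curve from ``(fraction %, trace)`` pairs.

    The response of each trace is its site C-channel signal divided by the
    mean site C signal of the 100% (fully converted) samples.  Replicate
    traces at the same fraction all enter the OLS fit.
    """
    fractions = []
    raw = []
    for frac, trace in labeled_traces:
        if not 0.0 <= frac <= 100.0:
            raise ValueError(f"mixture fraction {frac} outside [0, 100]")
        fractions.append(float(frac))
        raw.append(_site_response(trace, site))
    distinct = sorted(set(fractions))
    if len(distinct) < 3:
        raise ValueError("need at least 3 distinct mixture fractions")
    top = [r for f, r in zip(fractions, raw) if f == 100.0]
    if not top:
        raise ValueError("a 100% calibration sample is required to define L'")
    l_prime = float(np.mean(top))
    if l_prime <= 0:
        raise ValueError("100% calibration sample has zero C signal")
    responses = np.asarray(raw) / l_prime
    if np.allclose(responses, responses[0]):
        raise ValueError("all responses identical; degenerate calibration")
    fit = stats.linregress(np.asarray(fractions), responses)
    return StandardCurve(
        fractions=tuple(fractions),
        responses=tuple(responses),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        reference_signal=l_prime,
        site=site,
    )


def estimate_retention_from_curve(
    curve: StandardCurve, trace: ChromatogramTrace, site: int | None = None
) -> RetentionEstimate:
    """Invert the standard curve to read the converted fraction of a sample.

    Only molecules that still carried the unnatural pair convert to C-G under
    bridge PCR, while molecules mutated in vivo carry the mutation signature —
    so the converted fraction of the recovered sample's bridge product *is*
    the retention F.
    """
    if site is None:
        site = curve.site
    if curve.slope == 0:
        raise ValueError("standard curve has zero slope; cannot invert")
    response = _site_response(trace, site) / curve.reference_signal
    lo, hi = min(curve.responses), max(curve.responses)
    span = hi - lo
    if response < lo - 0.1 * span or response > hi + 0.1 * span:
        warnings.warn(
            f"response {response:.3f} outside calibrated range by >10%; extrapolating",
            stacklevel=2,
        )
    fraction = (response - curve.intercept) / curve.slope
    fraction = min(max(fraction, 0.0), 100.0)
    return RetentionEstimate(
        site=site, L=curve.reference_signal, R=response * curve.reference_signal,
        ratio=response, F=fraction / 100.0,
        method=RetentionMethod.STANDARD_CURVE, sample=trace.name,
    )


def mean_curve_retention(curve: StandardCurve, traces, site: int | None = None) -> float:
    """Average the curve estimate over replicate traces of one sample."""
    return float(np.mean([estimate_retention_from_curve(curve, t, site).F for t in traces]))
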