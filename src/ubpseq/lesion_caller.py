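"""AP-site / dU lesion calling from replacement-PCR substitution signatures.

A lesion excised and refilled with TPT3 reads as C under bridge PCR and as A
under NaM-only PCR.  Per-site substitution ratios are computed for a damaged
sample and an undamaged control, the control is subtracted as background, and
a site is called when every observable signature channel clears a threshold.
Reference G and T expose both channels; reference A exposes only the C
channel and reference C only the A channel (the other would coincide with
the reference base itself).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import NATURAL_BASES

_BASE_INDEX = {b: i for i, b in enumerate(NATURAL_BASES)}

#: observable signature channels per reference base
OBSERVABLE = {"G": ("C", "A"), "T": ("C", "A"), "A": ("C",), "C": ("A",)}


@dataclass
class MutationProfile:
    """Per-position substitution ratios with control background subtracted.

    ``sample_ratio`` / ``control_ratio`` are (L, 4) base fractions (each row
    sums to 1 at covered positions); ``subtracted`` is
    ``max(sample - control, 0)`` for the non-reference bases and 0 at the
    reference base.  Positions below the coverage minimum are masked.
    """

    reference: str
    sample_ratio: np.ndarray
    control_ratio: np.ndarray
    subtracted: np.ndarray
    sample_coverage: np.ndarray
    control_coverage: np.ndarray
    masked: np.ndarray

    def __len__(self) -> int:
        return len(self.reference)

    def subtracted_ratio(self, position: int, base: str) -> float:
        return float(self.subtracted[position, _BASE_INDEX[base]])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, ref in enumerate(self.reference):
            for b in NATURAL_BASES:
                if b == ref:
                    continue
                j = _BASE_INDEX[b]
                rows.append(
                    (i, ref, b, self.sample_ratio[i, j], self.control_ratio[i, j],
                     self.subtracted[i, j], int(self.sample_coverage[i]),
                     int(self.control_coverage[i]), bool(self.masked[i]))
                )
        return pd.DataFrame(
            rows,
            columns=["pos", "ref", "alt", "sample_ratio", "control_ratio",
                     "subtracted", "sample_coverage", "control_coverage", "masked"],
        )


def _ratios(counts: np.ndarray) -> tuple:
    counts = np.asarray(counts, dtype=float)
    cov = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(cov[:, None] > 0, counts / np.maximum(cov, 1)[:, None], 0.0)
    return ratio, cov


def mutation_ratios(
    sample_counts,
    control_counts,
    reference: str,
    min_coverage: int = 100,
) -> MutationProfile:
    """Build a background-subtracted mutation profile from pileup counts.

    ``sample_counts`` and ``control_counts`` are (L, 4) arrays of A,C,G,T
    counts per position.  Subtraction is clamped at zero, making it
    idempotent and never negative.
    """
    sample_counts = np.asarray(sample_counts)
    control_counts = np.asarray(control_counts)
    L = len(reference)
    if sample_counts.shape != (L, 4) or control_counts.shape != (L, 4):
        raise ValueError("pileup counts must match the reference length (L, 4)")
    s_ratio, s_cov = _ratios(sample_counts)
    c_ratio, c_cov = _ratios(control_counts)
    if s_cov.sum() == 0 and c_cov.sum() == 0:
        raise ValueError("zero coverage everywhere")
    sub = np.clip(s_ratio - c_ratio, 0.0, 1.0)
    ref_idx = np.fromiter((_BASE_INDEX[b] for b in reference), dtype=int, count=L)
    sub[np.arange(L), ref_idx] = 0.0
    masked = (s_cov < min_coverage) | (c_cov < min_coverage)
    return MutationProfile(
        reference=reference,
        sample_ratio=s_ratio,
        control_ratio=c_ratio,
        subtracted=sub,
        sample_coverage=s_cov,
        control_coverage=c_cov,
        masked=masked,
    )


@dataclass(frozen=True)
class LesionCall:
    position: int
    reference_base: str
    c_signature: float | None  # bridge-assay subtracted ref->C ratio
    a_signature: float | None  # NaM-only subtracted ref->A ratio
    observable: tuple
    called: bool
    overlap: bool
    single_channel: bool


def call_lesions(
    bridge_profile: MutationProfile,
    nam_profile: MutationProfile | None = None,
    threshold: float = 0.02,
) -> list:
    """Call lesion sites from one or both assay profiles.

    A site is called when every observable signature channel that has data
    clears the subtracted-ratio threshold; sites with a single usable channel
    are annotated ``single_channel``.  ``overlap`` marks sites where both
    channels pass (the corroborated calls).  Raising the threshold never adds
    calls (monotonicity).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if nam_profile is not None and nam_profile.reference != bridge_profile.reference:
        raise ValueError("profiles do not share coordinates")
    out = []
    for i, ref in enumerate(bridge_profile.reference):
        if bridge_profile.masked[i] or (nam_profile is not None and nam_profile.masked[i]):
            continue
        obs = OBSERVABLE[ref]
        c_val = bridge_profile.subtracted_ratio(i, "C") if "C" in obs else None
        a_val = (
            nam_profile.subtracted_ratio(i, "A")
            if (nam_profile is not None and "A" in obs)
            else None
        )
        channels = [v for v in (c_val, a_val) if v is not None]
        if not channels:
            continue
        called = all(v >= threshold for v in channels)
        overlap = len(channels) == 2 and called
        if called:
            out.append(
                LesionCall(
                    position=i,
                    reference_base=ref,
                    c_signature=c_val,
                    a_signature=a_val,
                    observable=obs,
                    called=True,
                    overlap=overlap,
                    single_channel=len(channels) == 1,
                )
            )
    return out


def dual_trace_lesion_readout(bridge_trace, nam_trace, reference: str) -> dict:
    """Per-dU-site verdict from a pair of Sanger traces.

    ``reference`` marks dU positions with the letter U.  A TPT3-labelled site
    reads C under bridge PCR and A under NaM-only PCR; an unlabelled dU pairs
    with A during PCR and reads T under both.  Any other pattern is
    inconsistent.
    """
    du_positions = [i for i, b in enumerate(reference) if b == "U"]
    if not du_positions:
        raise ValueError("reference marks no dU positions (letter U)")
    verdicts = {}
    b_calls = bridge_trace.primary if hasattr(bridge_trace, "primary") else list(bridge_trace)
    n_calls = nam_trace.primary if hasattr(nam_trace, "primary") else list(nam_trace)
    for pos in du_positions:
        bb, nb = b_calls[pos], n_calls[pos]
        if bb == "C" and nb == "A":
            verdicts[pos] = "labeled"
        elif bb == "T" and nb == "T":
            verdicts[pos] = "unlabeled"
        else:
            verdicts[pos] = "inconsistent"
    return verdicts
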