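"""Deep-sequencing analysis of the NNN-X-NNN amplicon.

Reads carry a fixed anchor on each side of a seven-base cassette: three
random bases, the replacement-PCR outcome at the unnatural-base position,
and three more random bases.  With 4^6 = 4096 possible flank combinations,
tallying the outcome base per context yields the transformation-preference
profile; normalising to 10^6 reads makes tallies comparable across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import NATURAL_BASES, decode_context

_BASE_INDEX = {b: i for i, b in enumerate(NATURAL_BASES)}

N_CONTEXTS = 4096
FLANK_POSITIONS = (-3, -2, -1, 0, 1, 2, 3)  # 0 is the unnatural-base centre


@dataclass(frozen=True)
class ContextExtraction:
    status: str  # ok | no_left_anchor | no_right_anchor | multi_anchor | bad_gap | bad_base
    upstream: str | None = None
    center: str | None = None
    downstream: str | None = None

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def extract_context(read: str, left_anchor: str, right_anchor: str) -> ContextExtraction:
    """Split a read into (upstream 3-mer, centre base, downstream 3-mer).

    Both anchors must match exactly and exactly once, with exactly seven
    bases between them; anything else is a rejection with a reason code.
    """
    if not left_anchor or not right_anchor:
        raise ValueError("anchors must be non-empty")
    li = read.find(left_anchor)
    if li < 0:
        return ContextExtraction("no_left_anchor")
    if read.find(left_anchor, li + 1) >= 0:
        return ContextExtraction("multi_anchor")
    ri = read.find(right_anchor)
    if ri < 0:
        return ContextExtraction("no_right_anchor")
    if read.find(right_anchor, ri + 1) >= 0:
        return ContextExtraction("multi_anchor")
    gap = read[li + len(left_anchor) : ri]
    if len(gap) != 7:
        return ContextExtraction("bad_gap")
    if set(gap) - set(NATURAL_BASES):
        return ContextExtraction("bad_base")
    return ContextExtraction("ok", gap[:3], gap[3], gap[4:])


@dataclass
class ContextTally:
    """Counts of the observed centre base per (upstream, downstream) context.

    ``counts`` has shape (4096, 4): row = context code, column = A,C,G,T.
    """

    counts: np.ndarray
    kept: int
    discarded: dict = field(default_factory=dict)
    normalization: float = 1.0
    rounding_residual: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (N_CONTEXTS, 4):
            raise ValueError("counts must have shape (4096, 4)")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def context_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def distinct_contexts(self) -> int:
        return int((self.context_totals > 0).sum())

    def to_frame(self, observed_only: bool = True) -> pd.DataFrame:
        rows = []
        for code in range(N_CONTEXTS):
            if observed_only and self.context_totals[code] == 0:
                continue
            up, down = decode_context(code)
            rows.append((up, down, *self.counts[code]))
        return pd.DataFrame(rows, columns=["context_up", "context_down", *NATURAL_BASES])


def tally_contexts(reads, left_anchor: str, right_anchor: str) -> ContextTally:
    """Tally centre-base counts per context over a read collection."""
    counts = np.zeros((N_CONTEXTS, 4), dtype=np.int64)
    discarded: dict = {}
    kept = 0
    code_cache = _BASE_INDEX
    for read in reads:
        hit = extract_context(read, left_anchor, right_anchor)
        if not hit.ok:
            discarded[hit.status] = discarded.get(hit.status, 0) + 1
            continue
        code = 0
        for b in hit.upstream:
            code = code * 4 + code_cache[b]
        for b in hit.downstream:
            code = code * 4 + code_cache[b]
        counts[code, code_cache[hit.center]] += 1
        kept += 1
    if kept == 0:
        raise ValueError("no reads passed anchor extraction")
    return ContextTally(counts=counts, kept=kept, discarded=discarded)


def normalize_to(tally: ContextTally, target: float = 1_000_000) -> ContextTally:
    """Scale all counts by target/total, rounding half-to-even per cell.

    The residual between the target and the rounded sum is reported, never
    silently redistributed.
    """
    total = tally.total
    if total <= 0:
        raise ValueError("cannot normalise an empty tally")
    scale = target / total
    scaled = np.round(tally.counts * scale).astype(np.int64)  # round-half-to-even
    return ContextTally(
        counts=scaled,
        kept=tally.kept,
        discarded=dict(tally.discarded),
        normalization=scale,
        rounding_residual=float(target - scaled.sum()),
    )


def context_summary(tally: ContextTally, bin_width: int = 10) -> dict:
    """Median/mean per observed context, histogram, and read-through ratio."""
    totals = tally.context_totals
    observed = totals[totals > 0]
    if observed.size == 0:
        raise ValueError("empty tally")
    edges = np.arange(0, observed.max() + 2 * bin_width, bin_width)
    hist, _ = np.histogram(observed, bins=edges)
    return {
        "median": float(np.median(observed)),
        "mean": float(observed.mean()),
        "distinct_contexts": int(observed.size),
        "read_through_ratio": float(observed.size / N_CONTEXTS),
        "histogram": {"bin_edges": edges.tolist(), "counts": hist.tolist()},
        "total": tally.total,
    }


def _context_digit_marginals(tally: ContextTally) -> np.ndarray:
    """(6, 4) weighted base counts for the six flank digits of the context."""
    totals = tally.context_totals
    codes = np.arange(N_CONTEXTS)
    out = np.zeros((6, 4))
    c = codes.copy()
    for digit in range(5, -1, -1):  # least-significant digit is downstream[2]
        out[digit] = np.bincount(c % 4, weights=totals, minlength=4)
        c //= 4
    return out


def base_position_frequencies(tally: ContextTally) -> pd.DataFrame:
    """7x4 base-frequency table at positions -3..-1, centre, +1..+3.

    Flank rows give the base composition of the random flanks; the centre row
    is the transformation-outcome distribution.  Rows sum to 1.
    """
    flanks = _context_digit_marginals(tally)
    center = tally.counts.sum(axis=0).astype(float)
    table = np.vstack([flanks[:3], center, flanks[3:]])
    table = table / table.sum(axis=1, keepdims=True)
    return pd.DataFrame(table, index=list(FLANK_POSITIONS), columns=list(NATURAL_BASES))


def dinucleotide_frequencies(tally: ContextTally, side: str) -> pd.Series:
    """Read counts per adjacent dinucleotide window on one side.

    ``side='upstream'`` uses positions -2,-1 (the two bases immediately
    before the centre); ``'downstream'`` uses +1,+2.  Sums to the total kept
    reads of the tally.
    """
    if side not in ("upstream", "downstream"):
        raise ValueError("side must be 'upstream' or 'downstream'")
    totals = tally.context_totals
    codes = np.arange(N_CONTEXTS)
    # digits (most significant first): u0 u1 u2 d0 d1 d2
    if side == "upstream":
        first = (codes // 4**4) % 4   # u1 (position -2)
        second = (codes // 4**3) % 4  # u2 (position -1)
    else:
        first = (codes // 4**2) % 4   # d0 (position +1)
        second = (codes // 4**1) % 4  # d1 (position +2)
    pair_code = first * 4 + second
    counts = np.bincount(pair_code, weights=totals, minlength=16)
    index = [a + b for a in NATURAL_BASES for b in NATURAL_BASES]
    return pd.Series(counts, index=index, name=side)


def transformation_proportions(tally: ContextTally, min_count: int = 10) -> pd.DataFrame:
    """Per-context outcome proportion vector over A,C,G,T.

    Contexts below ``min_count`` reads are flagged low-coverage, not dropped.
    Proportions sum to 1 per reported context.
    """
    totals = tally.context_totals
    rows = []
    for code in np.flatnonzero(totals > 0):
        up, down = decode_context(int(code))
        n = totals[code]
        props = tally.counts[code] / n
        rows.append((up, down, *props, int(n), bool(n < min_count)))
    return pd.DataFrame(
        rows,
        columns=["context_up", "context_down", *[f"p{b}" for b in NATURAL_BASES],
                 "count", "low_coverage"],
    )


def classify_dual_location_support(
    bridge_tally: ContextTally, nam_tally: ContextTally
) -> tuple:
    """Per-context dual-location support and the overall supported fraction.

    A context supports dual location when its modal outcome is G under the
    bridge assay and T under the NaM-only assay (strict plurality; ties are
    unsupported and flagged).  The fraction is taken over contexts observed
    in both tallies.
    """
    b_tot = bridge_tally.context_totals
    n_tot = nam_tally.context_totals
    common = np.flatnonzero((b_tot > 0) & (n_tot > 0))
    if common.size == 0:
        raise ValueError("tallies share no observed context")
    rows = []
    n_supported = 0
    for code in common:
        bc = bridge_tally.counts[code]
        nc = nam_tally.counts[code]
        b_tie = (bc == bc.max()).sum() > 1
        n_tie = (nc == nc.max()).sum() > 1
        b_modal = NATURAL_BASES[int(np.argmax(bc))]
        n_modal = NATURAL_BASES[int(np.argmax(nc))]
        supported = (not b_tie) and (not n_tie) and b_modal == "G" and n_modal == "T"
        n_supported += supported
        up, down = decode_context(int(code))
        rows.append(
            (up, down, b_modal, float(bc.max() / bc.sum()), n_modal,
             float(nc.max() / nc.sum()), b_tie or n_tie, supported)
        )
    df = pd.DataFrame(
        rows,
        columns=["context_up", "context_down", "bridge_modal", "bridge_modal_prop",
                 "nam_modal", "nam_modal_prop", "tie", "supports_dual_location"],
    )
    return df, n_supported / common.size
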