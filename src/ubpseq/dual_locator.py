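"""Dual location of TPT3-NaM pairs from two replacement-PCR products.

Bridge PCR (isoTAT + NaM) converts the pair to G-C; NaM-only PCR converts it
to T-A.  Comparing the two products base-by-base therefore gives a strand-
resolved signature at every unnatural site: on the strand that carried NaM
the bridge product reads G and the NaM-only product reads T, while a pair on
the complementary strand reads C / A.  Any other disagreement pattern is not
a pair signature.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

from Bio import Align

from .synthetic_data import UbpSequence
from .trace_retention import ChromatogramTrace


class Verdict(enum.Enum):
    UBP_ON_READ_STRAND = "ubp_nam_strand"     # bridge G / nam-only T
    UBP_ON_COMPLEMENT = "ubp_tpt3_strand"     # bridge C / nam-only A
    NATURAL = "natural"
    MUTATION = "mutation"
    AMBIGUOUS = "ambiguous"


_FLIP = {
    Verdict.UBP_ON_READ_STRAND: Verdict.UBP_ON_COMPLEMENT,
    Verdict.UBP_ON_COMPLEMENT: Verdict.UBP_ON_READ_STRAND,
}


@dataclass(frozen=True)
class SiteSignature:
    position: int  # 0-based on the read strand
    bridge_base: str
    nam_only_base: str
    verdict: Verdict
    bridge_secondary: str | None = None
    nam_secondary: str | None = None
    mixed: bool = False
    reference_base: str | None = None


def classify_site_signature(bridge_base: str, nam_only_base: str) -> Verdict:
    """Pure signature truth table (total over {A,C,G,T} x {A,C,G,T})."""
    if bridge_base == nam_only_base:
        return Verdict.NATURAL
    if bridge_base == "G" and nam_only_base == "T":
        return Verdict.UBP_ON_READ_STRAND
    if bridge_base == "C" and nam_only_base == "A":
        return Verdict.UBP_ON_COMPLEMENT
    return Verdict.AMBIGUOUS


@dataclass(frozen=True)
class ProductPairing:
    """Position-wise pairing of the two product sequences.

    ``columns`` holds (i, j) index pairs into the bridge and NaM-only
    sequences; gapped columns carry None on one side and are excluded from
    signature calling.
    """

    columns: tuple
    identity: float

    @property
    def gapped(self) -> int:
        return sum(1 for i, j in self.columns if i is None or j is None)


def _as_string(product) -> str:
    if isinstance(product, ChromatogramTrace):
        return "".join(product.primary)
    if isinstance(product, UbpSequence):
        return product.bases
    return str(product)


def align_products(bridge_seq, nam_seq, reference=None) -> ProductPairing:
    """Pair the two products positionally; fall back to global alignment
    (match +1, mismatch -1, gap -2) when lengths differ.

    The replacement chemistry conserves length, so unequal lengths indicate
    an indel artefact; gapped columns are excluded with a warning.  Identity
    below 80% raises (likely wrong sample pairing).
    """
    b, n = _as_string(bridge_seq), _as_string(nam_seq)
    if not b or not n:
        raise ValueError("empty product sequence")
    if len(b) == len(n):
        columns = tuple((i, i) for i in range(len(b)))
        matches = sum(1 for x, y in zip(b, n) if x == y)
        identity = matches / len(b)
    else:
        aligner = Align.PairwiseAligner(
            mode="global", match_score=1, mismatch_score=-1,
            open_gap_score=-2, extend_gap_score=-2,
        )
        aln = aligner.align(b, n)[0]
        columns = tuple(_alignment_columns(aln))
        aligned = [(i, j) for i, j in columns if i is not None and j is not None]
        matches = sum(1 for i, j in aligned if b[i] == n[j])
        identity = matches / max(len(aligned), 1)
        warnings.warn(
            f"products differ in length; {len(columns) - len(aligned)} gapped "
            "columns excluded from signature calling",
            stacklevel=2,
        )
    if identity < 0.80:
        raise ValueError(f"alignment identity {identity:.2f} < 0.80; wrong sample pairing?")
    return ProductPairing(columns=columns, identity=identity)


def _alignment_columns(aln):
    """Yield (i, j) column pairs (None on the gapped side) of a pairwise
    Bio.Align alignment."""
    ia = iter(range(len(aln.target)))
    ib = iter(range(len(aln.query)))
    a_gapped = aln[0]
    b_gapped = aln[1]
    for ca, cb in zip(a_gapped, b_gapped):
        i = next(ia) if ca != "-" else None
        j = next(ib) if cb != "-" else None
        yield (i, j)


def call_ubp_sites(
    bridge, nam_only, reference=None, secondary_threshold: float = 0.2
) -> list:
    """Call unnatural-pair sites by comparing the two products.

    Inputs may be sequences or chromatogram traces; with traces, secondary
    peaks mark mixed (partial-retention) sites.  A reference distinguishes a
    one-sided change (ordinary mutation) from a pair signature; positions
    where both products agree with each other but differ from the reference
    are reported as mutations.
    """
    pairing = align_products(bridge, nam_only, reference)
    b_seq, n_seq = _as_string(bridge), _as_string(nam_only)
    b_sec = bridge.secondary if isinstance(bridge, ChromatogramTrace) else [None] * len(b_seq)
    n_sec = nam_only.secondary if isinstance(nam_only, ChromatogramTrace) else [None] * len(n_seq)
    ref = _as_string(reference) if reference is not None else None
    out = []
    for i, j in pairing.columns:
        if i is None or j is None:
            continue  # gapped columns never produce UBP calls
        bb, nb = b_seq[i], n_seq[j]
        rb = ref[i] if ref is not None and i < len(ref) else None
        verdict = classify_site_signature(bb, nb)
        if verdict is Verdict.NATURAL:
            if rb is not None and rb not in "XY" and bb != rb:
                verdict = Verdict.MUTATION  # both products changed identically
            else:
                continue
        elif verdict is Verdict.AMBIGUOUS and rb is not None and rb not in "XY":
            if (bb == rb) != (nb == rb) and (bb == rb or nb == rb):
                verdict = Verdict.MUTATION  # only one product differs from reference
        mixed = b_sec[i] is not None or n_sec[j] is not None
        out.append(
            SiteSignature(
                position=i,
                bridge_base=bb,
                nam_only_base=nb,
                verdict=verdict,
                bridge_secondary=b_sec[i],
                nam_secondary=n_sec[j],
                mixed=mixed,
                reference_base=rb,
            )
        )
    return out


def flip_verdict(verdict: Verdict) -> Verdict:
    """Verdict of the same site observed from the complementary strand."""
    return _FLIP.get(verdict, verdict)
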