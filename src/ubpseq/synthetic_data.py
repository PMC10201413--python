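"""Synthetic inputs for the bridge-base sequencing pipeline.

Everything the pipeline consumes can be generated here with the statistical
structure the wet-lab assays assume: 134-mer templates carrying 1-3 TPT3-NaM
pairs (X = NaM, Y = TPT3), replacement-PCR product populations under the
bridge (X -> G) and NaM-only (X -> T) regimes, mixed-population Sanger traces,
deep-sequencing amplicon reads with randomised NNN-X-NNN flanks, lesion read
sets with C/A replacement signatures, and Michaelis-Menten kinetics tables.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .trace_retention import ChromatogramTrace

NATURAL_BASES = "ACGT"
EXTENDED_BASES = "ACGTXY"
_COMPLEMENT = str.maketrans("ACGTXY", "TGCAYX")
_BASE_INDEX = {b: i for i, b in enumerate(NATURAL_BASES)}
_BASE_BYTES = np.frombuffer(NATURAL_BASES.encode(), dtype=np.uint8)

#: Fixed synthetic 134-mer backbone shared by the template presets (a
#: stand-in: assay oligonucleotide sequences are typically proprietary).
BACKBONE_134 = (
    "TTCGCGCTTCCTCTTGCACCAGTCCATCGTTACCACAAAGACCAGCGATCGCATAGAGTGCTCAAACCCT"
    "AAACCGCTTATGAACAAGTATACGTCACTATCTTTTTACTTTTGTAGCGCTCTCTTATTATGGC"
)

#: Anchors flanking the randomised NNN-X-NNN cassette of the UN amplicon.
UN_LEFT_ANCHOR = BACKBONE_134[51:63]
UN_RIGHT_ANCHOR = BACKBONE_134[70:82]
UN_SITE = 66  # 0-based position of X in the UN / 1N templates


def reverse_complement(seq: str) -> str:
    """Reverse-complement over the extended alphabet (A<->T, C<->G, X<->Y)."""
    return seq.translate(_COMPLEMENT)[::-1]


class Strand(enum.Enum):
    SENSE = "sense"
    ANTISENSE = "antisense"


@dataclass(frozen=True)
class UbpSequence:
    """A nucleotide sequence over {A,C,G,T,X,Y} with known strand identity.

    ``ubp_positions`` is derived from the letters, so the invariant that it
    lists exactly the X/Y positions holds by construction.
    """

    bases: str
    name: str = "seq"
    strand: Strand = Strand.SENSE

    def __post_init__(self) -> None:
        bad = set(self.bases) - set(EXTENDED_BASES)
        if bad:
            raise ValueError(f"illegal letters {sorted(bad)}; alphabet is {EXTENDED_BASES}")

    @property
    def ubp_positions(self) -> tuple:
        return tuple(i for i, b in enumerate(self.bases) if b in "XY")

    def reverse_complement(self) -> "UbpSequence":
        other = Strand.ANTISENSE if self.strand is Strand.SENSE else Strand.SENSE
        return UbpSequence(reverse_complement(self.bases), name=self.name, strand=other)

    def __len__(self) -> int:
        return len(self.bases)

    def __getitem__(self, i):
        return self.bases[i]


class TransformationMode(enum.Enum):
    UBP = "ubp"            # keep X/Y (ordinary unnatural-base PCR)
    BRIDGE = "bridge"      # isoTAT + NaM: X -> G on the sense strand
    NAM_ONLY = "nam_only"  # NaM alone: X -> T on the sense strand
    TPT3_ONLY = "tpt3_only"  # TPT3 alone: messy, near-uniform outcomes
    NATURAL = "natural"    # no unnatural letters allowed


def _check_probs(vec: np.ndarray) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (4,) or (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-9:
        raise ValueError("probability vector must be non-negative and sum to 1")
    return vec


def context_code(up: str, down: str) -> int:
    """Encode an (upstream 3-mer, downstream 3-mer) pair as 0..4095."""
    code = 0
    for b in up + down:
        code = code * 4 + _BASE_INDEX[b]
    return code


def decode_context(code: int) -> tuple:
    mers = []
    for _ in range(6):
        mers.append(NATURAL_BASES[code % 4])
        code //= 4
    s = "".join(reversed(mers))
    return s[:3], s[3:]


@dataclass
class TransformationModel:
    """Per-context outcome distribution for the base written at a sense X.

    ``table`` maps (upstream 3-mer, downstream 3-mer) to a probability vector
    over A,C,G,T; unlisted contexts use ``default``.  ``retention`` is the
    fraction of molecules that still carry the unnatural pair after the
    replacement PCR (a molecule-level Bernoulli split; no cycle dynamics).
    """

    mode: TransformationMode
    default: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    table: dict = field(default_factory=dict)
    retention: float = 0.0

    def __post_init__(self) -> None:
        self.default = _check_probs(self.default)
        self.table = {k: _check_probs(v) for k, v in self.table.items()}
        if not 0.0 <= self.retention <= 1.0:
            raise ValueError("retention must lie in [0, 1]")

    def outcome_probs(self, up: str, down: str) -> np.ndarray:
        return self.table.get((up, down), self.default)

    def prob_matrix(self) -> np.ndarray:
        """Dense (4096, 4) matrix of outcome probabilities per context code."""
        mat = np.tile(self.default, (4096, 1))
        for (up, down), vec in self.table.items():
            mat[context_code(up, down)] = vec
        return mat

    # -- stock models -------------------------------------------------------

    @classmethod
    def point_mass(cls, mode: TransformationMode, base: str, retention: float = 0.0):
        vec = np.zeros(4)
        vec[_BASE_INDEX[base]] = 1.0
        return cls(mode=mode, default=vec, retention=retention)

    @classmethod
    def bridge_default(cls, retention: float = 0.0):
        return cls.point_mass(TransformationMode.BRIDGE, "G", retention)

    @classmethod
    def nam_only_default(cls, retention: float = 0.0):
        return cls.point_mass(TransformationMode.NAM_ONLY, "T", retention)

    @classmethod
    def tpt3_only_default(cls):
        return cls(mode=TransformationMode.TPT3_ONLY)

    @classmethod
    def bridge_context_biased(cls, retention: float = 0.0):
        """Bridge regime with context-dependent imperfection: mostly G
        (well over 66% per context) but CGG/GGG-downstream contexts flip to a
        modal A outcome.  Magnitudes are configuration values, not claims."""
        table = {}
        for code in range(4096):
            up, down = decode_context(code)
            if down in ("CGG", "GGG"):
                table[(up, down)] = np.array([0.55, 0.05, 0.30, 0.10])
        return cls(
            mode=TransformationMode.BRIDGE,
            default=np.array([0.10, 0.04, 0.78, 0.08]),
            table=table,
            retention=retention,
        )

    @classmethod
    def nam_context_biased(cls, retention: float = 0.0):
        """NaM-only regime: mostly T (over 60% per context), with all
        GGG-downstream and half of the GGA-downstream contexts flipped to a
        modal A outcome."""
        table = {}
        for code in range(4096):
            up, down = decode_context(code)
            if down == "GGG" or (down == "GGA" and up[0] in "AC"):
                table[(up, down)] = np.array([0.55, 0.08, 0.12, 0.25])
        return cls(
            mode=TransformationMode.NAM_ONLY,
            default=np.array([0.12, 0.05, 0.08, 0.75]),
            table=table,
            retention=retention,
        )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UbpSite:
    """One unnatural-base site of a template preset.

    ``context`` is the immediate-neighbour triple in compact form (e.g.
    ``GXA`` = G upstream, X, A downstream); ``retention``
    is the in vivo retention of the pair at that site and ``mutation_base``
    the sense-strand base that replaces a lost NaM.
    """

    position: int
    letter: str = "X"
    context: str | None = None  # e.g. "GXA"; None = leave backbone neighbours
    retention: float = 1.0
    mutation_base: str = "A"


@dataclass(frozen=True)
class TemplatePreset:
    name: str
    length: int = 134
    sites: tuple = ()
    random_flanks: bool = False  # UN design: NNN up/downstream per molecule
    pcr_carry: float = 1.0  # UBP carry-through of the attenuation assay


def _preset(name, sites, **kw):
    return TemplatePreset(name=name, sites=tuple(sites), **kw)


PRESETS = {
    "natural": _preset("natural", []),
    "1N": _preset("1N", [UbpSite(UN_SITE, context="GXA")]),
    "2N": _preset("2N", [UbpSite(55), UbpSite(77)]),
    "3N": _preset(
        "3N",
        [UbpSite(45, context="GXA"), UbpSite(66, context="TXT"), UbpSite(87, context="CXT")],
    ),
    "UN": _preset("UN", [UbpSite(UN_SITE)], random_flanks=True),
    # In vivo replicated plasmids: per-site retentions the assays should recover.
    "plasmid-A": _preset(
        "plasmid-A",
        [UbpSite(UN_SITE, context="GXA", retention=0.88, mutation_base="A")],
        pcr_carry=0.82 / 0.88,
    ),
    "plasmid-B": _preset(
        "plasmid-B",
        [
            UbpSite(45, context="GXA", retention=0.72, mutation_base="A"),
            UbpSite(66, context="TXT", retention=0.76, mutation_base="T"),
            UbpSite(87, context="CXT", retention=0.075, mutation_base="A"),
        ],
    ),
}

#: dU-lesion references (synthetic stand-ins; dU sits at T positions).
LESION_PRESETS = {
    "KRAS-1U": {
        "reference": BACKBONE_134[20:100],
        "du_positions": (41,),
    },
    "134-2U": {
        "reference": BACKBONE_134,
        "du_positions": (48, 88),
    },
}


class UnknownPresetError(KeyError):
    pass


def make_template(design, seed: int | None = None, **custom) -> UbpSequence:
    """Build a template from a preset name or a custom specification.

    Custom form: ``make_template("custom", length=10, ubp_positions=[3],
    letters="X", flank_triples={3: "GXA"})``.  The UN preset draws its NNN
    flanks uniformly at random (deterministic given ``seed``).
    """
    if design == "custom":
        length = custom["length"]
        positions = list(custom.get("ubp_positions", []))
        letters = custom.get("letters", "X" * len(positions))
        triples = custom.get("flank_triples", {})
        preset = TemplatePreset(
            name="custom",
            length=length,
            sites=tuple(
                UbpSite(p, letter=l, context=triples.get(p)) for p, l in zip(positions, letters)
            ),
        )
    else:
        try:
            preset = PRESETS[design]
        except KeyError:
            raise UnknownPresetError(f"unknown preset {design!r}") from None
    rng = np.random.default_rng(seed)

    if preset.length == 134:
        bases = list(BACKBONE_134)
    else:
        bases = list("".join(rng.choice(list(NATURAL_BASES), preset.length)))
    for site in preset.sites:
        if not 0 <= site.position < preset.length:
            raise ValueError(f"UBP position {site.position} outside sequence")
        bases[site.position] = site.letter
        if site.context is not None:
            if not 0 < site.position < preset.length - 1:
                raise ValueError("flank triple needs a neighbour on both sides")
            up, x, down = site.context
            if x != site.letter:
                raise ValueError(f"context {site.context} conflicts with letter {site.letter}")
            bases[site.position - 1] = up
            bases[site.position + 1] = down
        if preset.random_flanks:
            lo, hi = site.position - 3, site.position + 4
            if lo < 63 or hi > 70:  # NNN cassette must stay between the anchors
                raise ValueError("random flanks conflict with the fixed anchors")
            flanks = rng.choice(list(NATURAL_BASES), 6)
            bases[lo : site.position] = flanks[:3]
            bases[site.position + 1 : hi] = flanks[3:]
    return UbpSequence("".join(bases), name=preset.name)


def get_preset(name: str) -> TemplatePreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise UnknownPresetError(f"unknown preset {name!r}") from None


# ---------------------------------------------------------------------------
# Replacement-PCR product populations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationMember:
    """One sequence species of a product population.

    ``stop`` marks Sanger signal termination: the molecule contributes channel
    signal only at positions < stop (models an unconverted unnatural pair).
    """

    seq: str
    weight: float
    stop: int | None = None


@dataclass
class PcrPool:
    """Aggregated replacement-PCR products: converted natural-alphabet
    sequences with counts, plus the unconverted (still UBP-bearing) tally."""

    products: dict  # natural sequence -> molecule count
    n_unconverted: int
    template: UbpSequence
    mode: TransformationMode

    @property
    def n_converted(self) -> int:
        return sum(self.products.values())

    def to_population(self, include_unconverted: bool = True) -> list:
        """Weighted population for trace simulation.  Unconverted molecules
        enter as a terminated species stopping at the first unnatural site."""
        total = self.n_converted + (self.n_unconverted if include_unconverted else 0)
        members = [
            PopulationMember(seq, count / total) for seq, count in sorted(self.products.items())
        ]
        if include_unconverted and self.n_unconverted:
            stop = min(self.template.ubp_positions)
            filler = self.template.bases.replace("X", "A").replace("Y", "A")
            members.append(
                PopulationMember(filler, self.n_unconverted / total, stop=stop)
            )
        return members


def _sample_outcomes(model, template, pos, n, rng):
    """Outcome bases (indices into ACGT) at one X/Y site for n molecules."""
    seq = template.bases
    letter = seq[pos]
    if letter == "Y":
        # The pair is written on the complementary strand: sample for the X on
        # the antisense strand (revcomp context), then complement the result.
        rc = reverse_complement(seq)
        return 3 - _sample_outcomes(model, UbpSequence(rc, strand=Strand.ANTISENSE),
                                    len(seq) - 1 - pos, n, rng)
    up, down = seq[max(pos - 3, 0) : pos], seq[pos + 1 : pos + 4]
    if len(up) == 3 and len(down) == 3 and not (set(up + down) & set("XY")):
        probs = model.outcome_probs(up, down)
    else:
        probs = model.default  # truncated or unnatural neighbours: default vector
    return rng.choice(4, size=n, p=probs)


def simulate_pcr_product(
    template: UbpSequence, model: TransformationModel, n_molecules: int, seed: int | None = None
) -> PcrPool:
    """Simulate a replacement-PCR product population.

    With retention r, Binomial(n, r) molecules stay unconverted (still
    UBP-bearing, reported separately); the rest convert every X/Y position to
    a natural base drawn from the model, copying natural positions verbatim.
    """
    if len(template) == 0:
        raise ValueError("empty template")
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    positions = template.ubp_positions
    if model.mode is TransformationMode.NATURAL and positions:
        raise ValueError("NATURAL mode cannot amplify a UBP-bearing template")
    rng = np.random.default_rng(seed)
    n_unconverted = int(rng.binomial(n_molecules, model.retention)) if positions else 0
    n_conv = n_molecules - n_unconverted
    if not positions or n_conv == 0:
        products = {template.bases: n_conv} if n_conv else {}
        return PcrPool(products, n_unconverted, template, model.mode)
    draws = {pos: _sample_outcomes(model, template, pos, n_conv, rng) for pos in positions}
    products: dict = {}
    chars = np.array(list(template.bases))
    seq_matrix = np.tile(chars, (n_conv, 1))
    for pos, idx in draws.items():
        seq_matrix[:, pos] = np.array(list(NATURAL_BASES))[idx]
    for row in seq_matrix:
        s = "".join(row)
        products[s] = products.get(s, 0) + 1
    return PcrPool(products, n_unconverted, template, model.mode)


# ---------------------------------------------------------------------------
# Sanger trace simulation
# ---------------------------------------------------------------------------


def simulate_trace(
    population,
    noise_sd: float = 0.0,
    seed: int | None = None,
    amplitude: float = 1000.0,
    secondary_threshold: float = 0.2,
    name: str = "trace",
) -> ChromatogramTrace:
    """Render a mixed population as a four-channel chromatogram.

    Channel intensity for base b at each position is the mixture fraction of
    (non-terminated) molecules carrying b there, times the peak amplitude,
    perturbed by signal-proportional Gaussian noise truncated at zero.
    """
    if noise_sd < 0:
        raise ValueError("negative noise_sd")
    if isinstance(population, PcrPool):
        population = population.to_population()
    members = [
        m if isinstance(m, PopulationMember) else PopulationMember(*m) for m in population
    ]
    if not members:
        raise ValueError("empty population")
    lengths = {len(m.seq) for m in members}
    if len(lengths) != 1:
        raise ValueError("population sequences must all have equal length")
    total = sum(m.weight for m in members)
    if abs(total - 1.0) > 1e-6:
        raise ValueError("population weights must sum to 1")
    L = lengths.pop()
    frac = np.zeros((L, 4))
    pos_idx = np.arange(L)
    for m in members:
        idx = np.fromiter((_BASE_INDEX[b] for b in m.seq), dtype=int, count=L)
        live = pos_idx < (m.stop if m.stop is not None else L)
        frac[pos_idx[live], idx[live]] += m.weight
    channels = frac * amplitude
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        channels = channels * (1.0 + rng.normal(0.0, noise_sd, size=channels.shape))
        channels = np.clip(channels, 0.0, None)
    return ChromatogramTrace(channels, name=name, secondary_threshold=secondary_threshold)


# ---------------------------------------------------------------------------
# Deep-sequencing reads of the UN amplicon
# ---------------------------------------------------------------------------


@dataclass
class ReadSet:
    """Amplicon reads kept as plain strings (FASTQ qualities are constant I)."""

    sequences: list
    name: str = "reads"

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def to_fastq(self, path) -> None:
        with open(path, "w") as fh:
            qual = None
            for i, seq in enumerate(self.sequences):
                if qual is None or len(qual) != len(seq):
                    qual = "I" * len(seq)
                fh.write(f"@{self.name}_{i}\n{seq}\n+\n{qual}\n")


def simulate_un_context_draws(
    n_reads: int,
    model: TransformationModel,
    seed: int | None = None,
    context_weights=None,
):
    """Vectorised core of the UN simulation: per-read context codes (0..4095)
    and outcome base indices.  ``context_weights`` optionally biases which
    contexts are sequenced (uniform by default)."""
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    if context_weights is None:
        codes = rng.integers(0, 4096, size=n_reads)
    else:
        w = np.asarray(context_weights, dtype=float)
        codes = rng.choice(4096, size=n_reads, p=w / w.sum())
    pmat = model.prob_matrix()
    cum = np.cumsum(pmat, axis=1)
    u = rng.random(n_reads)
    outcomes = (u[:, None] > cum[codes]).sum(axis=1)
    return codes, outcomes


def simulate_un_reads(
    n_reads: int,
    model: TransformationModel,
    read_length: int | None = None,
    seed: int | None = None,
    context_weights=None,
    left_anchor: str = UN_LEFT_ANCHOR,
    right_anchor: str = UN_RIGHT_ANCHOR,
) -> ReadSet:
    """Simulate UN-amplicon reads: left anchor + NNN + outcome + NNN + right
    anchor (+ backbone filler up to ``read_length``)."""
    core = len(left_anchor) + len(right_anchor) + 7
    if read_length is None:
        read_length = core
    if read_length < core:
        raise ValueError(f"read_length must be >= {core}")
    codes, outcomes = simulate_un_context_draws(n_reads, model, seed, context_weights)
    # decode context codes into six flank base indices
    cassette = np.empty((n_reads, 7), dtype=np.uint8)
    c = codes.copy()
    for col in (6, 5, 4, 2, 1, 0):  # base-4 digits, most significant first
        cassette[:, col] = _BASE_BYTES[c % 4]
        c //= 4
    # column order after filling: digits written least-significant-first into
    # 6,5,4 (downstream) then 2,1,0 (upstream); centre column 3 is the outcome
    cassette[:, 3] = _BASE_BYTES[outcomes]
    blob = cassette.tobytes().decode()
    filler = (BACKBONE_134 * (read_length // 134 + 1))[: read_length - core]
    reads = [
        left_anchor + blob[7 * i : 7 * i + 7] + right_anchor + filler for i in range(n_reads)
    ]
    return ReadSet(reads, name="UN")


# ---------------------------------------------------------------------------
# Lesion read sets
# ---------------------------------------------------------------------------

SIGNATURE_BASE = {"BRIDGE": "C", "NAM_ONLY": "A"}


@dataclass
class LesionReadSet:
    """Damaged + control read matrices (uint8 base indices, shape (n, L))."""

    damaged: np.ndarray
    control: np.ndarray
    reference: str
    assay_mode: str
    damage_sites: tuple
    damage_fractions: tuple
    unobservable_sites: tuple

    def pileup(self, which: str = "damaged") -> np.ndarray:
        """(L, 4) base counts over reads of the chosen set."""
        mat = self.damaged if which == "damaged" else self.control
        counts = np.zeros((mat.shape[1], 4), dtype=np.int64)
        for b in range(4):
            counts[:, b] = (mat == b).sum(axis=0)
        return counts

    def reads(self, which: str = "damaged") -> ReadSet:
        mat = self.damaged if which == "damaged" else self.control
        blob = _BASE_BYTES[mat].tobytes().decode()
        L = mat.shape[1]
        return ReadSet([blob[i * L : (i + 1) * L] for i in range(mat.shape[0])], name=which)


def simulate_lesion_reads(
    reference: str,
    damage_sites,
    damage_fraction,
    assay_mode: str = "BRIDGE",
    n_reads: int = 1000,
    seed: int | None = None,
    background: float = 0.005,
) -> LesionReadSet:
    """Simulate reads from a lesion-bearing sample plus an undamaged control.

    At each damage site the reference base is replaced by the replacement-PCR
    signature base (C under the bridge regime, A under NaM-only) in a
    ``damage_fraction`` of reads; a uniform background error rate applies
    everywhere in both sets.  A site whose reference base already equals the
    signature base is unobservable: flagged, but still generated.
    """
    if assay_mode not in SIGNATURE_BASE:
        raise ValueError("assay_mode must be BRIDGE or NAM_ONLY")
    sites = tuple(int(s) for s in damage_sites)
    fracs = np.broadcast_to(np.asarray(damage_fraction, dtype=float), (len(sites),))
    if ((fracs < 0) | (fracs > 1)).any():
        raise ValueError("damage fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ref_idx = np.fromiter((_BASE_INDEX[b] for b in reference), dtype=np.uint8)
    L = len(ref_idx)
    sig = _BASE_INDEX[SIGNATURE_BASE[assay_mode]]

    def one_set(damaged: bool) -> np.ndarray:
        mat = np.tile(ref_idx, (n_reads, 1))
        if damaged:
            for s, f in zip(sites, fracs):
                hit = rng.random(n_reads) < f
                mat[hit, s] = sig
        if background > 0:
            err = rng.random((n_reads, L)) < background
            shift = rng.integers(1, 4, size=err.sum()).astype(np.uint8)
            mat[err] = (mat[err] + shift) % 4
        return mat

    damaged = one_set(True)
    control = one_set(False)
    unobservable = tuple(s for s in sites if ref_idx[s] == sig)
    return LesionReadSet(
        damaged, control, reference, assay_mode, sites, tuple(fracs), unobservable
    )


# ---------------------------------------------------------------------------
# Kinetics tables
# ---------------------------------------------------------------------------


def default_dilution_series(top: float = 100.0, n: int = 8) -> np.ndarray:
    """Two-fold dilution series in uM, highest concentration first."""
    return top / 2.0 ** np.arange(n)


def simulate_kinetics(
    vmax: float,
    km: float,
    concentrations=None,
    cv: float = 0.0,
    seed: int | None = None,
    label: str = "",
):
    """Michaelis-Menten velocity table: v_i = Vmax c_i/(Km + c_i) (1 + eps_i),
    eps_i ~ Normal(0, cv).  Units: uM and %incor/min."""
    import pandas as pd

    if vmax <= 0 or km <= 0:
        raise ValueError("vmax and km must be positive")
    if concentrations is None:
        concentrations = default_dilution_series()
    c = np.asarray(concentrations, dtype=float)
    if (c <= 0).any():
        raise ValueError("concentrations must be positive")
    v = vmax * c / (km + c)
    if cv > 0:
        rng = np.random.default_rng(seed)
        v = v * (1.0 + rng.normal(0.0, cv, size=v.shape))
    return pd.DataFrame(
        {"concentration_uM": c, "velocity_pct_per_min": v, "label": label or "sample"}
    )


# ---------------------------------------------------------------------------
# Retention-workflow trace sets (plasmid presets + mixture calibration)
# ---------------------------------------------------------------------------

DEFAULT_MIXTURE_FRACTIONS = (100.0, 90.0, 80.0, 70.0, 60.0, 50.0, 40.0, 30.0, 20.0, 0.0)


def antisense_site(position: int, length: int = 134) -> int:
    return length - 1 - position


def _antisense_variants(preset: TemplatePreset):
    """Antisense-strand sequence variants of the bridge product of a
    replicated plasmid: per site, retained molecules read C (bridge-converted
    pair) and lost molecules read the complement of the sense mutation base."""
    sense = make_template(preset.name).bases
    anti = reverse_complement(sense)
    site_specs = []
    for s in preset.sites:
        a_pos = antisense_site(s.position, len(sense))
        lost = s.mutation_base.translate(_COMPLEMENT)
        site_specs.append((a_pos, s.retention, "C", lost))
    return anti, site_specs


def plasmid_bridge_population(preset_name: str) -> list:
    """Exact mixture population (antisense strand) of the bridge-PCR product
    of a replicated plasmid preset: independent per-site retention."""
    preset = get_preset(preset_name)
    anti, site_specs = _antisense_variants(preset)
    # expand the per-site retained/lost outcomes into a product distribution
    members = [PopulationMember(anti, 1.0)]
    for a_pos, retention, kept_base, lost_base in site_specs:
        new = []
        for m in members:
            kept = m.seq[:a_pos] + kept_base + m.seq[a_pos + 1 :]
            lost = m.seq[:a_pos] + lost_base + m.seq[a_pos + 1 :]
            if retention > 0:
                new.append(PopulationMember(kept, m.weight * retention))
            if retention < 1:
                new.append(PopulationMember(lost, m.weight * (1 - retention)))
        members = new
    # any unnatural letters away from sites should not remain
    members = [
        PopulationMember(m.seq.replace("X", "G").replace("Y", "C"), m.weight) for m in members
    ]
    return members


def calibration_mixture_population(preset_name: str, fraction: float) -> list:
    """Mixture of fully bridge-converted product (fraction %, antisense C at
    every site) with natural-template product (antisense G at every site)."""
    preset = get_preset(preset_name)
    anti, site_specs = _antisense_variants(preset)
    converted = anti
    natural = anti
    for a_pos, _, kept_base, _ in site_specs:
        converted = converted[:a_pos] + kept_base + converted[a_pos + 1 :]
        natural = natural[:a_pos] + "G" + natural[a_pos + 1 :]
    converted = converted.replace("X", "G").replace("Y", "C")
    natural = natural.replace("X", "G").replace("Y", "C")
    f = fraction / 100.0
    members = []
    if f > 0:
        members.append(PopulationMember(converted, f))
    if f < 1:
        members.append(PopulationMember(natural, 1 - f))
    return members


def simulate_calibration_traces(
    preset_name: str,
    fractions=DEFAULT_MIXTURE_FRACTIONS,
    noise_sd: float = 0.0,
    seed: int | None = None,
    replicates: int = 3,
) -> list:
    """(fraction, trace) pairs for the mixture standard curve (replicated)."""
    rng = np.random.default_rng(seed)
    out = []
    for frac in fractions:
        pop = calibration_mixture_population(preset_name, frac)
        for r in range(replicates):
            out.append(
                (
                    frac,
                    simulate_trace(
                        pop, noise_sd, seed=int(rng.integers(2**31)),
                        name=f"{preset_name}_mix{frac:g}_{r}",
                    ),
                )
            )
    return out


def simulate_plasmid_traces(
    preset_name: str, noise_sd: float = 0.0, seed: int | None = None, replicates: int = 3
) -> list:
    """Replicate antisense bridge-product traces of a replicated plasmid."""
    rng = np.random.default_rng(seed)
    pop = plasmid_bridge_population(preset_name)
    return [
        simulate_trace(pop, noise_sd, seed=int(rng.integers(2**31)), name=f"{preset_name}_{r}")
        for r in range(replicates)
    ]


def simulate_attenuation_traces(
    preset_name: str, noise_sd: float = 0.0, seed: int | None = None
):
    """Sample + natural-control traces for the signal-attenuation assay.

    The sample is the unnatural-base PCR product of the recovered plasmid:
    molecules still carrying the pair terminate Sanger signal at the site, so
    the post-site/pre-site signal ratio reads the non-retained fraction.  The
    preset's ``pcr_carry`` models unnatural-base loss during that PCR.
    """
    preset = get_preset(preset_name)
    if len(preset.sites) != 1:
        raise ValueError("attenuation assay is defined for single-site presets")
    site = preset.sites[0]
    measured_retention = site.retention * preset.pcr_carry
    template = make_template(preset.name)
    anti = reverse_complement(template.bases)
    a_pos = antisense_site(site.position, len(template))
    readthrough = anti[:a_pos] + site.mutation_base.translate(_COMPLEMENT) + anti[a_pos + 1 :]
    readthrough = readthrough.replace("X", "G").replace("Y", "C")
    terminated = PopulationMember(readthrough, measured_retention, stop=a_pos)
    members = [PopulationMember(readthrough, 1.0 - measured_retention)]
    if measured_retention > 0:
        members.append(terminated)
    rng = np.random.default_rng(seed)
    sample = simulate_trace(members, noise_sd, seed=int(rng.integers(2**31)),
                            name=f"{preset_name}_ubp_pcr")
    control_seq = readthrough
    control = simulate_trace(
        [PopulationMember(control_seq, 1.0)], noise_sd, seed=int(rng.integers(2**31)),
        name="natural_control",
    )
    return sample, control
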