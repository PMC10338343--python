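"""Guide:target duplex representation, coordinates and duplex free energy.

Coordinate conventions used throughout the package
--------------------------------------------------

*Guide/target (g/t) space* is 1-based: g1 is the 5'-most guide nucleotide,
and t_i denotes the target nucleotide paired to g_i.  Because the duplex is
antiparallel, walking 5'->3' along the target visits tN ... t1.

*Transcript space* is 0-based, half-open.  If ``c`` is the transcript index
of t10 (the first nucleotide of the 3' cleavage product), then

    index(t_i) = c + 10 - i

so t11 sits at ``c - 1`` and t1 at ``c + 9``.  Slicing hydrolyses the
phosphodiester bond between t10 and t11; the 3' product starts at ``c`` and
carries the 5' monophosphate diagnostic of endonucleolytic cleavage.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Watson-Crick pairs, (guide, target).
WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
#: G:U wobble pairs, (guide, target).
WOBBLE_PAIRS = frozenset({("G", "U"), ("U", "G")})

GAS_CONSTANT_KCAL = 1.987e-3  # kcal / (mol K)
#: Binding reactions are run at 33 degrees C.
DEFAULT_TEMPERATURE_K = 306.15


def complement(base: str) -> str:
    """Watson-Crick complement of a single RNA base."""
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise ValueError(f"not an RNA base: {base!r}") from None


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA string."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def as_rna(seq: str) -> str:
    """Uppercase and convert T->U so DNA-spelled input is accepted."""
    return seq.upper().replace("T", "U")


class PairState(enum.Enum):
    """Per-position pairing state of a guide:target duplex."""

    WATSON_CRICK = "|"
    GU_WOBBLE = ":"
    MISMATCH = "."
    GUIDE_BULGE = "-"      # target deletion: guide nucleotide has no partner
    TARGET_BULGE = "+"     # target insertion opposite this step
    UNPAIRED_FLANK = " "

    def __str__(self) -> str:  # compact serialization symbol
        return self.value


_STATE_BY_SYMBOL = {s.value: s for s in PairState}


@dataclass(frozen=True)
class GuideRNA:
    """A small-RNA guide, 5'->3', 18-35 nt over {A,C,G,U}.

    ``abundance_pM`` is the intracellular concentration of the guide where
    known (absolute quantification via spike-ins), else ``None``.
    """

    name: str
    sequence: str
    abundance_pM: Optional[float] = None

    def __post_init__(self) -> None:
        seq = as_rna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ValueError(f"guide {self.name!r}: non-RNA characters {sorted(bad)}")
        if not 18 <= len(seq) <= 35:
            raise ValueError(
                f"guide {self.name!r}: length {len(seq)} outside [18, 35]"
            )
        if self.abundance_pM is not None and self.abundance_pM < 0:
            raise ValueError("abundance_pM must be nonnegative")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TargetSite:
    """A target RNA window, 5'->3'.

    ``site_start`` is the index (0-based) of the nucleotide opposite the
    highest-numbered guide position gN; walking 5'->3' from there visits
    tN ... t1 (antiparallel to the guide).
    """

    sequence: str
    site_start: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", as_rna(self.sequence))
        if self.site_start < 0:
            raise ValueError("site_start must be >= 0")

    def t_index(self, guide_len: int, i: int) -> int:
        """Index within ``sequence`` of t_i for a guide of length guide_len."""
        if not 1 <= i <= guide_len:
            raise ValueError(f"t{i} undefined for a {guide_len}-nt guide")
        return self.site_start + (guide_len - i)

    def t1_identity(self, guide_len: int) -> str:
        return self.sequence[self.t_index(guide_len, 1)]


@dataclass(frozen=True)
class PairingConfiguration:
    """Per-guide-position pairing states of one duplex.

    ``wobble_paired`` selects the contiguity convention: when True (the
    default used for binding-energy and candidate-site analyses) G:U wobbles
    count as paired; when False (the convention used to label mismatch
    geometries in cleavage-rate analyses) they count as mismatches.
    """

    states: tuple
    wobble_paired: bool = True
    t1: Optional[str] = None

    PAIRED_STATES = (PairState.WATSON_CRICK, PairState.GU_WOBBLE)

    def is_paired(self, i: int) -> bool:
        """Is guide position i (1-based) paired under the configured convention?"""
        s = self.states[i - 1]
        if s is PairState.WATSON_CRICK:
            return True
        if s is PairState.GU_WOBBLE:
            return self.wobble_paired
        return False

    @property
    def paired_count(self) -> int:
        return sum(self.is_paired(i) for i in range(1, len(self.states) + 1))

    @property
    def contiguous_span(self) -> Optional[tuple]:
        """(g_start, g_end) of the longest contiguous paired block, or None.

        Ties are broken toward the 5'-most block.
        """
        best = None
        start = None
        n = len(self.states)
        for i in range(1, n + 2):
            if i <= n and self.is_paired(i):
                if start is None:
                    start = i
            else:
                if start is not None:
                    length = i - start
                    if best is None or length > best[1] - best[0] + 1:
                        best = (start, i - 1)
                    start = None
        return best

    def paired_blocks(self) -> list:
        """All maximal contiguous paired blocks as (g_start, g_end), 5'->3'."""
        blocks = []
        start = None
        n = len(self.states)
        for i in range(1, n + 2):
            if i <= n and self.is_paired(i):
                if start is None:
                    start = i
            else:
                if start is not None:
                    blocks.append((start, i - 1))
                    start = None
        return blocks

    def to_string(self) -> str:
        return "".join(s.value for s in self.states)

    @classmethod
    def from_string(cls, s: str, wobble_paired: bool = True) -> "PairingConfiguration":
        try:
            states = tuple(_STATE_BY_SYMBOL[c] for c in s)
        except KeyError as e:
            raise ValueError(f"unknown pairing symbol {e.args[0]!r}") from None
        return cls(states=states, wobble_paired=wobble_paired)

    def __len__(self) -> int:
        return len(self.states)


def classify_pair(guide_base: str, target_base: str) -> PairState:
    """Classify one opposed base pair."""
    pair = (guide_base, target_base)
    if pair in WC_PAIRS:
        return PairState.WATSON_CRICK
    if pair in WOBBLE_PAIRS:
        return PairState.GU_WOBBLE
    return PairState.MISMATCH


def annotate_pairing(
    guide: GuideRNA,
    target: TargetSite,
    wobble_paired: bool = True,
) -> PairingConfiguration:
    """Classify every guide position against its opposed target nucleotide.

    The comparison is gapless: guide position g_i is opposed to the target
    nucleotide at ``target.site_start + (N - i)``.  Indel-containing
    configurations are expressed by constructing a
    :class:`PairingConfiguration` directly (for example from its compact
    string form); this annotator handles the substitution-only geometry that
    every high-throughput stage of the pipeline assumes.

    Raises
    ------
    ValueError
        If the target window is too short to oppose all guide positions.
    """
    n = len(guide)
    if target.site_start + n > len(target.sequence):
        raise ValueError(
            f"target too short: needs {target.site_start + n} nt to oppose "
            f"a {n}-nt guide starting at index {target.site_start}, "
            f"got {len(target.sequence)}"
        )
    states = []
    for i in range(1, n + 1):
        t_base = target.sequence[target.t_index(n, i)]
        states.append(classify_pair(guide.sequence[i - 1], t_base))
    return PairingConfiguration(
        states=tuple(states),
        wobble_paired=wobble_paired,
        t1=target.t1_identity(n),
    )


def cut_site_coordinates(guide: GuideRNA, target_index_of_t10: int):
    """Transcript-space coordinates implied by slicing between t10 and t11.

    Returns ``(five_prime_product_span, three_prime_product_start)`` where
    the 5' product span is the half-open interval ``(0, c)`` of the
    transcript upstream of the scissile bond and the 3' product starts at
    ``c`` (its 5' end carries the monophosphate).
    """
    c = target_index_of_t10
    if c < 0:
        raise ValueError("t10 index must be >= 0")
    return (0, c), c


def paired_region_span(guide_len: int, target_index_of_t10: int) -> tuple:
    """Half-open transcript interval covered by tN..t1 for a full duplex."""
    c = target_index_of_t10
    return (c + 10 - guide_len, c + 10)


def t_transcript_index(target_index_of_t10: int, i: int) -> int:
    """Transcript index of t_i given the index of t10."""
    return target_index_of_t10 + 10 - i


# ---------------------------------------------------------------------------
# Nearest-neighbour duplex free energy
# ---------------------------------------------------------------------------

# Watson-Crick/Watson-Crick stack free energies (kcal/mol, 37 C), indexed by
# the guide dinucleotide 5'->3' (the opposed target dinucleotide is implied).
# Turner-style parameters.
WC_STACKS = {
    "AA": -0.93, "AC": -2.24, "AG": -2.08, "AU": -1.10,
    "CA": -2.11, "CC": -3.26, "CG": -2.36, "CU": -2.08,
    "GA": -2.35, "GC": -3.42, "GG": -3.26, "GU": -2.24,
    "UA": -1.33, "UC": -2.35, "UG": -2.11, "UU": -0.93,
}


@dataclass(frozen=True)
class EnergyModel:
    """Turner-style nearest-neighbour parameter set.

    Wobble-containing stacks use flat defaults rather than the full
    sequence-dependent table; internal loops are charged an initiation cost
    plus a per-mismatch term.  All parameters are overridable, and
    :func:`predict_duplex_energy` accepts any callable implementing the same
    interface as an external predictor hook.
    """

    wc_stacks: dict = field(default_factory=lambda: dict(WC_STACKS))
    one_wobble_stack: float = -1.20
    two_wobble_stack: float = -0.50
    duplex_init: float = 4.09
    terminal_au_penalty: float = 0.45
    loop_init: float = 1.70
    loop_per_mismatch: float = 1.10
    tag: str = "turner-nn-default"

    def stack(self, g_dinuc: str, s1: PairState, s2: PairState) -> float:
        wobbles = (s1 is PairState.GU_WOBBLE) + (s2 is PairState.GU_WOBBLE)
        if wobbles == 0:
            try:
                return self.wc_stacks[g_dinuc]
            except KeyError:
                raise ValueError(f"unknown dinucleotide step {g_dinuc!r}") from None
        if wobbles == 1:
            return self.one_wobble_stack
        return self.two_wobble_stack


DEFAULT_ENERGY_MODEL = EnergyModel()


@dataclass(frozen=True)
class DuplexEnergy:
    """Predicted standard free energy of duplex formation (kcal/mol)."""

    delta_G0: float
    model_tag: str


def predict_duplex_energy(
    guide: GuideRNA,
    target: TargetSite,
    config: Optional[PairingConfiguration] = None,
    model: EnergyModel = DEFAULT_ENERGY_MODEL,
) -> DuplexEnergy:
    """Nearest-neighbour free energy of the annotated duplex.

    The energy is the duplex initiation cost, plus stack terms summed over
    adjacent paired positions within each contiguous paired block, plus a
    terminal penalty for A:U or G:U closing pairs, plus an internal-loop
    charge for each mismatch run separating two blocks.  An empty pairing
    has energy 0 by convention.
    """
    if config is None:
        config = annotate_pairing(guide, target)
    blocks = config.paired_blocks()
    if not blocks:
        return DuplexEnergy(0.0, model.tag)
    g = guide.sequence
    e = model.duplex_init
    for (a, b) in blocks:
        for i in range(a, b):
            e += model.stack(g[i - 1 : i + 1], config.states[i - 1], config.states[i])
        for end in (a, b):
            if config.states[end - 1] is PairState.GU_WOBBLE or (
                g[end - 1] in "AU"
                and config.states[end - 1] is PairState.WATSON_CRICK
            ):
                e += model.terminal_au_penalty
    # internal loops between consecutive blocks
    for (_, b_prev), (a_next, _) in zip(blocks, blocks[1:]):
        n_mm = a_next - b_prev - 1
        e += model.loop_init + model.loop_per_mismatch * n_mm
    return DuplexEnergy(e, model.tag)


def kd_to_energy(kd_molar: float, temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """Standard binding free energy from a dissociation constant.

    Delta-G0 = R T ln(Kd / 1 M), with R = 1.987e-3 kcal/(mol K).  The default
    temperature is 306.15 K, matching the 33 C binding reactions.
    """
    if kd_molar <= 0:
        raise ValueError("Kd must be positive")
    return GAS_CONSTANT_KCAL * temperature_K * math.log(kd_molar)
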