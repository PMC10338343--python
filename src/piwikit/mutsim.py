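"""Transposon-mutagenesis escape simulation.

A transposon consensus accumulates random single-nucleotide substitutions
(synonymous-only inside its ORFs, since non-synonymous changes would break
the element itself) while the small-RNA repertoire stays fixed.  After each
substitution the number of guides still predicted to direct cleavage is
recorded, under the empirically derived competence rules:

* 26-nt piRNA: <= 6 total mismatches, at any positions;
* 21-nt siRNA (the piRNA 5' prefix): <= 5 total mismatches, <= 1 mismatch
  within the seed (g2-g8), and no mismatch at g9, g10, g11 or g13.

The decay of competent-guide counts with substitution load quantifies how
easily a transposon escapes each silencing pathway by mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Data import CodonTable

DNA_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(DNA_BASES)}
_CODE_BASE = np.array(list(DNA_BASES))
_DNA_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

SIRNA_LEN = 21
PIRNA_MAX_MISMATCH = 6
SIRNA_MAX_MISMATCH = 5
SIRNA_SEED_MAX_MISMATCH = 1          # seed = g2-g8
SIRNA_CRITICAL_POSITIONS = (9, 10, 11, 13)   # must be matched


def _codon_to_aa() -> Dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    aa = dict(table.forward_table)
    for stop in table.stop_codons:
        aa[stop] = "*"
    return aa


_CODON_AA = _codon_to_aa()


@dataclass(frozen=True)
class ConsensusSequence:
    """A transposon consensus (DNA) with ORF intervals.

    ORF intervals are 0-based half-open and in frame with their start; a
    proposal inside any ORF must be synonymous in every ORF containing it.
    """

    name: str
    sequence: str
    orf_intervals: Tuple[Tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - set(DNA_BASES)
        if bad:
            raise ValueError(f"non-DNA characters {sorted(bad)}")
        for start, end in self.orf_intervals:
            if not (0 <= start < end <= len(seq)):
                raise ValueError(f"ORF ({start}, {end}) outside sequence")
            if (end - start) % 3:
                raise ValueError(f"ORF ({start}, {end}) length not divisible by 3")


@dataclass(frozen=True)
class MutationSpectrum:
    """Normalized weights for the 12 ordered base substitutions.

    The default weights encode a 2:1 transition:transversion ratio, a
    coarse summary of mammalian germline mutation biases; any spectrum can
    be supplied as {(from, to): weight}.
    """

    weights: Tuple[Tuple[str, str, float], ...]

    @classmethod
    def from_dict(cls, w: Dict[Tuple[str, str], float]) -> "MutationSpectrum":
        items = []
        total = sum(w.values())
        if total <= 0 or any(v < 0 for v in w.values()):
            raise ValueError("weights must be nonnegative with positive sum")
        for (a, b), v in sorted(w.items()):
            if a == b or a not in DNA_BASES or b not in DNA_BASES:
                raise ValueError(f"invalid substitution {a}->{b}")
            items.append((a, b, v / total))
        return cls(weights=tuple(items))

    @classmethod
    def default(cls, ts_tv_ratio: float = 2.0) -> "MutationSpectrum":
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        w = {}
        for a in DNA_BASES:
            for b in DNA_BASES:
                if a != b:
                    w[(a, b)] = ts_tv_ratio if (a, b) in transitions else 1.0
        return cls.from_dict(w)

    def row(self, base: str) -> np.ndarray:
        """Unnormalized weights toward each of ACGT from ``base``."""
        out = np.zeros(4)
        for a, b, v in self.weights:
            if a == base:
                out[_BASE_CODE[b]] = v
        return out


@dataclass
class GuideRepertoire:
    """Antisense guides with fixed anchors on the unmutated consensus.

    ``anchors`` holds the leftmost consensus index covered by each 26-nt
    guide; guide g1 opposes consensus position anchor+25 and g26 opposes
    the anchor itself.  Simulated siRNAs are the 21-nt 5' prefixes of the
    same guides.  Anchors never shift because only substitutions are
    simulated.
    """

    guides: List[str]              # RNA, 5'->3', 26 nt
    anchors: np.ndarray            # (n,), int
    abundances_pM: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.guides) != len(self.anchors):
            raise ValueError("guides and anchors length mismatch")
        for g in self.guides:
            if len(g) != 26:
                raise ValueError("piRNA guides must be 26 nt")

    def __len__(self) -> int:
        return len(self.guides)


class _CompetenceChecker:
    """Vectorized guide-vs-sequence mismatch counting at fixed anchors."""

    def __init__(self, repertoire: GuideRepertoire, seq_len: int,
                 wobble_is_match: bool = False):
        n = len(repertoire)
        glen = 26
        idx = np.empty((n, glen), np.intp)
        expected = np.empty((n, glen), np.uint8)
        wobble = np.full((n, glen), 255, np.uint8)
        for gi, (guide, anchor) in enumerate(
            zip(repertoire.guides, repertoire.anchors)
        ):
            if anchor < 0 or anchor + glen > seq_len:
                raise ValueError(f"guide {gi} anchor outside sequence")
            g_dna = guide.upper().replace("U", "T")
            for i in range(1, glen + 1):   # guide position g_i
                pos = anchor + glen - i
                idx[gi, i - 1] = pos
                expected[gi, i - 1] = _BASE_CODE[_DNA_COMP[g_dna[i - 1]]]
                if wobble_is_match:
                    # G:U (guide G, target U->sense T) and U:G wobbles
                    if g_dna[i - 1] == "G":
                        wobble[gi, i - 1] = _BASE_CODE["T"]
                    elif g_dna[i - 1] == "T":
                        wobble[gi, i - 1] = _BASE_CODE["G"]
        self.idx = idx
        self.expected = expected
        self.wobble = wobble
        seed_cols = [i - 1 for i in range(2, 9)]
        self.seed_cols = np.array(seed_cols)
        self.critical_cols = np.array([p - 1 for p in SIRNA_CRITICAL_POSITIONS])

    def mismatches(self, seq_codes: np.ndarray) -> np.ndarray:
        at = seq_codes[self.idx]
        return (at != self.expected) & (at != self.wobble)

    def counts(self, seq_codes: np.ndarray) -> Tuple[int, int]:
        mm = self.mismatches(seq_codes)
        pi_ok = mm.sum(axis=1) <= PIRNA_MAX_MISMATCH
        mm21 = mm[:, :SIRNA_LEN]
        si_ok = (
            (mm21.sum(axis=1) <= SIRNA_MAX_MISMATCH)
            & (mm[:, self.seed_cols].sum(axis=1) <= SIRNA_SEED_MAX_MISMATCH)
            & ~mm[:, self.critical_cols].any(axis=1)
        )
        return int(pi_ok.sum()), int(si_ok.sum())


def encode_sequence(seq: str) -> np.ndarray:
    return np.array([_BASE_CODE[b] for b in seq.upper().replace("U", "T")],
                    np.uint8)


def decode_sequence(codes: np.ndarray) -> str:
    return "".join(_CODE_BASE[codes])


def count_competent(
    sequence: str,
    repertoire: GuideRepertoire,
    wobble_is_match: bool = False,
) -> Tuple[int, int]:
    """(n_piRNA, n_siRNA) competent guides against the given sequence.

    G:U wobbles count as mismatches by default (the competence rules speak
    of mismatches without a wobble carve-out).
    """
    codes = encode_sequence(sequence)
    checker = _CompetenceChecker(repertoire, len(codes), wobble_is_match)
    return checker.counts(codes)


def _orf_memberships(consensus: ConsensusSequence) -> List[List[Tuple[int, int]]]:
    member: List[List[Tuple[int, int]]] = [[] for _ in consensus.sequence]
    for start, end in consensus.orf_intervals:
        for p in range(start, end):
            member[p].append((start, end))
    return member


def _synonymous_everywhere(codes: np.ndarray, pos: int, new_code: int,
                           orfs: Sequence[Tuple[int, int]]) -> bool:
    for start, end in orfs:
        codon_start = start + ((pos - start) // 3) * 3
        codon = codes[codon_start : codon_start + 3]
        old = "".join(_CODE_BASE[codon])
        new = list(old)
        new[pos - codon_start] = _CODE_BASE[new_code]
        if _CODON_AA["".join(new)] != _CODON_AA[old]:
            return False
    return True


def mutate_step(
    codes: np.ndarray,
    spectrum: MutationSpectrum,
    orf_members: Sequence[Sequence[Tuple[int, int]]],
    rng: np.random.Generator,
    max_redraws: int = 100000,
) -> int:
    """Apply one accepted substitution in place; returns the position.

    A proposal draws a position uniformly and a replacement base from the
    spectrum row of the current base; proposals that are non-synonymous in
    any ORF containing the position are rejected and redrawn.
    """
    n = len(codes)
    for _ in range(max_redraws):
        pos = int(rng.integers(0, n))
        row = spectrum.row(_CODE_BASE[codes[pos]])
        total = row.sum()
        if total <= 0:
            continue
        new_code = int(rng.choice(4, p=row / total))
        if orf_members[pos] and not _synonymous_everywhere(
            codes, pos, new_code, orf_members[pos]
        ):
            continue
        codes[pos] = new_code
        return pos
    raise RuntimeError("no acceptable substitution found after bounded redraws")


@dataclass
class MutagenesisTrajectory:
    """Competent-guide counts along one simulated lineage."""

    n_pirna: np.ndarray            # (steps + 1,)
    n_sirna: np.ndarray
    seed: int


def simulate_lineage(
    consensus: ConsensusSequence,
    repertoire: GuideRepertoire,
    spectrum: Optional[MutationSpectrum] = None,
    steps: int = 1000,
    seed: int = 0,
    wobble_is_match: bool = False,
) -> MutagenesisTrajectory:
    """One lineage of ``steps`` accepted substitutions with per-step counts."""
    spectrum = spectrum or MutationSpectrum.default()
    rng = np.random.default_rng(seed)
    codes = encode_sequence(consensus.sequence)
    orf_members = _orf_memberships(consensus)
    checker = _CompetenceChecker(repertoire, len(codes), wobble_is_match)
    n_pi = np.empty(steps + 1, np.int64)
    n_si = np.empty(steps + 1, np.int64)
    n_pi[0], n_si[0] = checker.counts(codes)
    for s in range(1, steps + 1):
        mutate_step(codes, spectrum, orf_members, rng)
        n_pi[s], n_si[s] = checker.counts(codes)
    return MutagenesisTrajectory(n_pirna=n_pi, n_sirna=n_si, seed=seed)


def run_simulations(
    consensus: ConsensusSequence,
    repertoire: GuideRepertoire,
    spectrum: Optional[MutationSpectrum] = None,
    steps: int = 1000,
    n_simulations: int = 100,
    seed: int = 0,
    wobble_is_match: bool = False,
) -> List[MutagenesisTrajectory]:
    """Independent lineages; per-lineage seeds derive from ``seed``."""
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_simulations)]
    return [
        simulate_lineage(consensus, repertoire, spectrum, steps, cs, wobble_is_match)
        for cs in child_seeds
    ]


@dataclass
class DecayRate:
    """Percent of guides lost per substitution for one guide class.

    ``slope_of_means`` fits the mean fraction-competent trajectory;
    ``mean_of_slopes``/``median_of_slopes`` summarize per-lineage fits
    (the two aggregation orders in general differ; both are reported).
    """

    slope_of_means: float
    mean_of_slopes: float
    median_of_slopes: float
    iqr_of_slopes: Tuple[float, float]


def decay_rate(
    trajectories: Sequence[MutagenesisTrajectory],
    repertoire_size: int,
    guide_class: str = "pirna",
) -> DecayRate:
    """Least-squares decay of fraction-competent vs substitution count,
    expressed as percent of guides lost per substitution."""
    if not trajectories:
        raise ValueError("no trajectories")
    key = {"pirna": "n_pirna", "sirna": "n_sirna"}[guide_class]
    mat = np.stack([getattr(t, key) for t in trajectories]).astype(float)
    frac = mat / repertoire_size
    steps = np.arange(frac.shape[1])

    def pct_lost_per_step(y: np.ndarray) -> float:
        slope = np.polyfit(steps, y, 1)[0]
        return -slope * 100.0

    per_sim = np.array([pct_lost_per_step(row) for row in frac])
    q1, q3 = np.percentile(per_sim, [25, 75])
    return DecayRate(
        slope_of_means=pct_lost_per_step(frac.mean(axis=0)),
        mean_of_slopes=float(per_sim.mean()),
        median_of_slopes=float(np.median(per_sim)),
        iqr_of_slopes=(float(q1), float(q3)),
    )
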