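"""Transcript/transposon k-mer sharing.

For each k, the fraction of transcripts containing at least one exact
k-mer also present in a set of transposon consensus sequences.  A low
fraction at the minimum complementarity length that licenses slicing
(k >= 15) indicates that host transcripts are unlikely to be cleaved
inadvertently by transposon-targeting guides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence

VALID_BASES = set("ACGTU")
_COMP = str.maketrans("ACGTU", "TGCAA")


@dataclass(frozen=True)
class KmerOverlapReport:
    k: int
    n_transcripts: int
    n_with_shared_kmer: int
    strand_mode: str

    @property
    def fraction(self) -> float:
        return self.n_with_shared_kmer / self.n_transcripts


def _kmer_set(seq: str, k: int) -> set:
    """All k-mers of a sequence, skipping windows with ambiguity codes."""
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if set(kmer) <= VALID_BASES:
            out.add(kmer)
    return out


def _revcomp_dna(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def shared_kmer_fraction(
    transcripts: Mapping[str, str],
    consensus: Mapping[str, str],
    k_values: Sequence[int],
    strand_mode: str = "sense",
) -> List[KmerOverlapReport]:
    """Per-k fraction of transcripts sharing >= 1 k-mer with any consensus.

    ``strand_mode`` is 'sense' (consensus sense-strand k-mers only, the
    default) or 'both' (consensus k-mers from both strands).  Sequences are
    uppercased and compared in DNA spelling (U -> T).  A transcript counts
    at most once per k regardless of how many shared k-mers it contains.
    """
    if not transcripts or not consensus:
        raise ValueError("transcripts and consensus sets must be nonempty")
    if strand_mode not in ("sense", "both"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    tx = {name: s.upper().replace("U", "T") for name, s in transcripts.items()}
    cons = {name: s.upper().replace("U", "T") for name, s in consensus.items()}
    reports = []
    for k in sorted(k_values):
        ref: set = set()
        for seq in cons.values():
            ref |= _kmer_set(seq, k)
            if strand_mode == "both":
                ref |= _kmer_set(_revcomp_dna(seq), k)
        n_hit = 0
        for seq in tx.values():
            if any(
                seq[i : i + k] in ref for i in range(len(seq) - k + 1)
            ):
                n_hit += 1
        reports.append(KmerOverlapReport(
            k=k, n_transcripts=len(tx), n_with_shared_kmer=n_hit,
            strand_mode=strand_mode,
        ))
    return reports
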