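"""Seeded synthetic-data generators.

Every generator draws all randomness from a single seed and emits data
with the statistical structure the corresponding analysis stage assumes:
equilibrium-binding read counts across the piRISC concentration series,
exponential-depletion cleavage time courses, degradome cohorts (4 control
+ 4 mutant animals) with planted piRNA-guided cleavage events, and
log-normally distributed guide repertoires.  They exist so every estimator
in the package can be exercised against known ground truth without any
sequencing download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import rbns as _rbns
from .invivo import ConfigurationQuery
from .mutsim import ConsensusSequence, GuideRepertoire
from .pairing import (GuideRNA, PairState, WC_PAIRS, WOBBLE_PAIRS, complement,
                      reverse_complement)

RNA_BASES = "ACGU"


def _random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(RNA_BASES), size=n))


def _nonpairing_base(guide_base: str, rng: np.random.Generator) -> str:
    """A target base that neither Watson-Crick- nor wobble-pairs guide_base."""
    options = [
        b for b in RNA_BASES
        if (guide_base, b) not in WC_PAIRS and (guide_base, b) not in WOBBLE_PAIRS
    ]
    return str(rng.choice(options))


# ---------------------------------------------------------------------------
# Bind-'n-Seq
# ---------------------------------------------------------------------------


def gen_rbns_counts(
    true_kds_pM: Mapping[str, float],
    input_freqs: Mapping[str, float],
    depth: int = 1_000_000,
    concentrations_nM: Sequence[float] = _rbns.DEFAULT_CONCENTRATIONS_NM,
    library_nM: float = _rbns.DEFAULT_LIBRARY_NM,
    stock_nM: float = 1.0,
    seed: int = 0,
) -> _rbns.SiteCountTable:
    """Site-count table drawn from the equilibrium competition model.

    ``true_kds_pM`` and ``input_freqs`` map site labels (including
    ``no_site``) to the planted dissociation constants and library
    frequencies.  The input column is multinomial at ``depth``; each bound
    column is multinomial over p_i proportional to f_i * theta_i with the
    occupancy theta from the shared free-RISC conservation solution.
    ``stock_nM`` is the true active concentration at the top point of the
    dilution series.
    """
    labels = list(true_kds_pM)
    if set(labels) != set(input_freqs):
        raise ValueError("true_kds_pM and input_freqs must share keys")
    if _rbns.NO_SITE not in labels:
        raise ValueError("a no_site class is required")
    f = np.array([input_freqs[l] for l in labels], float)
    if not math.isclose(f.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("input frequencies must sum to 1")
    kds_nM = np.array([true_kds_pM[l] for l in labels], float) / 1e3
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations_nM, float)
    data = {"input": rng.multinomial(depth, f)}
    s_sites = f * library_nM
    cmax = conc.max() if conc.max() > 0 else 1.0
    for j, c in enumerate(conc):
        e_total = stock_nM * c / cmax
        if e_total == 0:
            # no-piRISC control lane: resamples the input composition
            p = f
        else:
            e_free = _rbns._free_risc(e_total, s_sites, kds_nM)
            theta = e_free / (e_free + kds_nM)
            p = f * theta
        data[f"bound_{j}"] = rng.multinomial(depth, p / p.sum())
    counts = pd.DataFrame(data, index=labels)
    return _rbns.SiteCountTable(counts=counts, concentrations_nM=tuple(conc),
                                library_nM=library_nM)


def gen_rbns_reads(
    catalog: _rbns.SiteCatalog,
    n_reads: int,
    plant_fraction: float = 0.5,
    seed: int = 0,
) -> List[str]:
    """Random-layout reads, a fraction of which carry one planted motif.

    Planted reads embed one catalog motif at a random position of the
    random region with deliberately non-pairing flanks; the rest of the
    read is random, so multi-motif and no-motif reads also arise, as in a
    real library.
    """
    rng = np.random.default_rng(seed)
    g = catalog.guide.sequence
    motifs = [(w.label, catalog.motif(w), w.g_start, w.g_end)
              for w in catalog.windows]
    if catalog.include_seed_8mer:
        motifs.append((_rbns.SEED_8MER, catalog.seed_8mer_motif(), 2, 8))
    reads = []
    for _ in range(n_reads):
        region = list(_random_rna(rng, _rbns.RANDOM_REGION_LEN))
        if rng.random() < plant_fraction:
            label, motif, g_start, g_end = motifs[rng.integers(len(motifs))]
            L = len(motif)
            if L <= _rbns.RANDOM_REGION_LEN - 2:
                start = int(rng.integers(1, _rbns.RANDOM_REGION_LEN - L))
                region[start : start + L] = motif
                # non-pairing flanks so the planted site is unambiguous
                if g_end + 1 <= len(g):
                    region[start - 1] = _nonpairing_base(g[g_end], rng)
                if g_start - 1 >= 1:
                    region[start + L] = _nonpairing_base(g[g_start - 2], rng)
        reads.append(_rbns.READ_PREFIX + "".join(region) + _rbns.READ_SUFFIX)
    return reads


# ---------------------------------------------------------------------------
# Cleave-'n-Seq
# ---------------------------------------------------------------------------


def gen_cns(
    true_k: Sequence[float],
    e_relative: Union[float, Sequence[float]] = 1.0,
    n_normalizers: int = 50,
    depth: int = 100_000,
    n_trials: int = 3,
    fast_times: Sequence[float] = (0.0, 1.0, 2.0, 4.0, 8.0),
    slow_times: Sequence[float] = (0.0, 20.0, 60.0, 120.0, 240.0, 480.0, 960.0),
    baseline_sigma: float = 0.25,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Cleavage time-course count table with planted per-variant rates.

    The uncleaved fraction of variant i at time t is 1 - E_i (1 - e^(-k t))
    (first-turnover burst with negligible steady-state flux); counts per
    sample are multinomial at ``depth`` over baseline-weighted uncleaved
    fractions.  Normalizer variants (<= 7-nt complementarity, uncleavable)
    are appended with k = 0.  Returns (counts, manifest); counts columns
    are a MultiIndex (trial, time_min) with trials f1..fN on the fast
    subset and s1..sN on the slow subset.
    """
    k = np.asarray(true_k, float)
    e_rel = np.broadcast_to(np.asarray(e_relative, float), k.shape)
    rng = np.random.default_rng(seed)
    n_var = len(k)
    ids = [f"v{i:04d}" for i in range(n_var)] + \
          [f"norm{i:03d}" for i in range(n_normalizers)]
    k_all = np.concatenate([k, np.zeros(n_normalizers)])
    e_all = np.concatenate([e_rel, np.ones(n_normalizers)])
    base = np.exp(rng.normal(0.0, baseline_sigma, size=len(ids)))

    cols = {}
    for subset, times in (("f", fast_times), ("s", slow_times)):
        for trial in range(1, n_trials + 1):
            for t in times:
                uncleaved = 1.0 - e_all * (1.0 - np.exp(-k_all * t))
                w = base * uncleaved
                cols[(f"{subset}{trial}", float(t))] = rng.multinomial(
                    depth, w / w.sum()
                )
    counts = pd.DataFrame(cols, index=ids)
    counts.columns = pd.MultiIndex.from_tuples(counts.columns,
                                               names=["trial", "time_min"])
    manifest = pd.DataFrame({
        "variant_id": ids,
        "true_k": k_all,
        "true_e_relative": e_all,
        "is_normalizer": [i >= n_var for i in range(len(ids))],
    }).set_index("variant_id")
    return counts, manifest


# ---------------------------------------------------------------------------
# Degradome cohort
# ---------------------------------------------------------------------------


@dataclass
class DegradomeCohort:
    """Synthetic degradome inputs plus planted truth.

    ``pirnas``: small-RNA prefix-group table (12 control + 9 mutant
    small-RNA replicates, abundance_pM); ``species``: 5'-monoP species
    with 4 control + 4 mutant degradome replicates; ``transcripts``:
    transcript id -> sequence; ``truth``: per planted site, the explaining
    piRNA, configuration label, set membership and whether the site was
    planted as decreased.
    """

    pirnas: pd.DataFrame
    species: pd.DataFrame
    transcripts: Dict[str, str]
    truth: pd.DataFrame


def _plant_site(guide_seq: str, query: ConfigurationQuery,
                rng: np.random.Generator) -> str:
    """Target window (5'->3', opposing tN..t1) realizing exactly the query.

    Positions g_start..g_end pair Watson-Crick except queried mismatches;
    every other position (including g_end + 1, the non-overlap flank) is
    deliberately non-pairing.
    """
    n = len(guide_seq)
    window = [""] * n
    mm = set(query.mismatch_at)
    for i in range(1, n + 1):
        if query.g_start <= i <= query.g_end and i not in mm:
            base = complement(guide_seq[i - 1])
        else:
            base = _nonpairing_base(guide_seq[i - 1], rng)
        window[n - i] = base   # t_i sits at window index n - i
    return "".join(window)


def gen_degradome(
    queries: Sequence[ConfigurationQuery] = (ConfigurationQuery(2, 18),),
    phi: Union[float, Mapping[str, float], Callable[[float], float]] = 0.4,
    background: float = 0.05,
    n_targeted_pirnas: int = 60,
    n_control_pirnas: int = 60,
    sites_per_query: int = 120,
    n_control_reps: int = 4,
    n_mutant_reps: int = 4,
    n_smallrna_control_reps: int = 12,
    n_smallrna_mutant_reps: int = 9,
    abundance_lognormal: Tuple[float, float] = (1.1, 1.2),   # ln-ppm mu, sigma
    pM_per_ppm: float = 30.0,
    decrease_fold: float = 16.0,
    replicate_cv: float = 0.08,
    seed: int = 0,
) -> DegradomeCohort:
    """Degradome cohort with planted cleavage signal.

    For each configuration class, ``sites_per_query`` sites are planted for
    the targeted piRNA set and the same number for the control set.  A
    targeted-set site is planted as decreased (mutant abundance =
    control / ``decrease_fold``) with probability ``phi`` -- the planted
    fraction cleaved -- while control-set sites are decreased with
    probability ``background``, emulating the sampling error of short-lived
    5'-monoP fragments.  ``phi`` may be a single probability, a mapping
    from configuration label to probability, or a callable of the
    explaining piRNA's abundance (pM), which produces
    concentration-dependent cleavage.  piRNA abundances are log-normal in
    ppm and converted to pM with a fixed spike-in-calibrated scale.
    """
    rng = np.random.default_rng(seed)

    def phi_for(label: str, abundance_pM: float) -> float:
        if callable(phi):
            return float(phi(abundance_pM))
        if isinstance(phi, Mapping):
            return float(phi[label])
        return float(phi)

    # --- piRNA prefix groups -------------------------------------------
    n_pirnas = n_targeted_pirnas + n_control_pirnas
    prefixes = []
    seen = set()
    while len(prefixes) < n_pirnas:
        p = _random_rna(rng, 25)
        if p not in seen:
            seen.add(p)
            prefixes.append(p)
    ppm = np.exp(rng.normal(*abundance_lognormal, size=n_pirnas))
    ppm = np.maximum(ppm, 1.0)      # all groups pass the >= 1 ppm filter
    targeted = np.arange(n_pirnas) < n_targeted_pirnas
    pi_rows = {}
    pi_rows["prefix25"] = prefixes
    pi_rows["unique_mapping"] = True
    for r in range(1, n_smallrna_control_reps + 1):
        pi_rows[f"control_ppm_{r}"] = np.maximum(
            ppm * rng.lognormal(0.0, replicate_cv, n_pirnas), 1.0
        )
    for r in range(1, n_smallrna_mutant_reps + 1):
        pi_rows[f"mutant_ppm_{r}"] = np.where(
            targeted, 0.01, ppm * rng.lognormal(0.0, replicate_cv, n_pirnas)
        )
    pirnas = pd.DataFrame(pi_rows)
    pirnas["abundance_pM"] = ppm * pM_per_ppm
    pirnas["targeted"] = targeted

    # --- transcripts with planted sites and 5'-monoP species -----------
    transcripts: Dict[str, str] = {}
    species_rows = []
    truth_rows = []
    site_id = 0
    for query in queries:
        for is_targeted_site in (True, False):
            pool = np.flatnonzero(targeted == is_targeted_site)
            for _ in range(sites_per_query):
                gi = int(rng.choice(pool))
                guide_seq = prefixes[gi]
                window = _plant_site(guide_seq, query, rng)
                left = _random_rna(rng, 30)
                right = _random_rna(rng, 30)
                tx_seq = left + window + right
                tx_id = f"tx{site_id:05d}"
                transcripts[tx_id] = tx_seq
                # window index of tN is len(left); t10 at +  (N - 10)
                coord = len(left) + len(guide_seq) - 10
                base_ppm = float(np.exp(rng.normal(0.5, 0.8))) + MIN_SPECIES
                p_dec = phi_for(query.label, float(ppm[gi] * pM_per_ppm)) \
                    if is_targeted_site else background
                decreased = bool(rng.random() < p_dec)
                row = {"species_id": f"sp{site_id:05d}",
                       "transcript": tx_id, "coordinate": coord}
                for r in range(1, n_control_reps + 1):
                    row[f"control_ppm_{r}"] = base_ppm * float(
                        rng.lognormal(0.0, replicate_cv)
                    )
                for r in range(1, n_mutant_reps + 1):
                    mut = base_ppm / decrease_fold if decreased else base_ppm
                    row[f"mutant_ppm_{r}"] = mut * float(
                        rng.lognormal(0.0, replicate_cv)
                    )
                species_rows.append(row)
                truth_rows.append({
                    "species_id": row["species_id"],
                    "config_label": query.label,
                    "explaining_prefix": guide_seq,
                    "targeted_set": is_targeted_site,
                    "planted_decreased": decreased,
                    "abundance_pM": float(ppm[gi] * pM_per_ppm),
                })
                site_id += 1
    return DegradomeCohort(
        pirnas=pirnas,
        species=pd.DataFrame(species_rows),
        transcripts=transcripts,
        truth=pd.DataFrame(truth_rows),
    )


MIN_SPECIES = 0.04   # species abundance floor (ppm), matching the retention rule


# ---------------------------------------------------------------------------
# Guide repertoires and consensus sequences
# ---------------------------------------------------------------------------


def gen_consensus(
    length: int = 6000,
    orf_fraction: float = 0.6,
    seed: int = 0,
    name: str = "synthetic_line",
) -> ConsensusSequence:
    """Random transposon-like consensus with one central ORF.

    The ORF spans ``orf_fraction`` of the sequence (rounded to codons) and
    contains no internal stop codons, so synonymous-only mutagenesis is
    well defined everywhere inside it.
    """
    rng = np.random.default_rng(seed)
    seq = list("".join(rng.choice(list("ACGT"), size=length)))
    orf_len = int(length * orf_fraction) // 3 * 3
    start = (length - orf_len) // 2
    from .mutsim import _CODON_AA  # standard genetic code
    non_stop = [c for c, aa in _CODON_AA.items() if aa != "*"]
    codons = rng.choice(non_stop, size=orf_len // 3)
    seq[start : start + orf_len] = list("".join(codons))
    return ConsensusSequence(
        name=name, sequence="".join(seq),
        orf_intervals=((start, start + orf_len),),
    )


def gen_repertoire(
    consensus: ConsensusSequence,
    n_guides: int = 300,
    abundance_lognormal: Tuple[float, float] = (4.0, 1.5),  # ln-pM mu, sigma
    seed: int = 0,
) -> GuideRepertoire:
    """Antisense 26-nt guides anchored uniformly along the consensus.

    Guides are exact reverse complements of their anchor window, so the
    whole repertoire starts fully competent; abundances are log-normal in
    pM, leaving a small highly abundant tail.
    """
    if len(consensus.sequence) < 26:
        raise ValueError("consensus shorter than a 26-nt guide")
    rng = np.random.default_rng(seed)
    anchors = rng.integers(0, len(consensus.sequence) - 26 + 1, size=n_guides)
    rna = consensus.sequence.replace("T", "U")
    guides = [reverse_complement(rna[a : a + 26]) for a in anchors]
    return GuideRepertoire(
        guides=guides,
        anchors=np.asarray(anchors, np.intp),
        abundances_pM=np.exp(rng.normal(*abundance_lognormal, size=n_guides)),
    )


def gen_transcriptome(
    n_transcripts: int = 50,
    length: int = 800,
    seed: int = 0,
) -> Dict[str, str]:
    """Random transcript set for k-mer sharing analyses."""
    rng = np.random.default_rng(seed)
    return {
        f"tx{i:04d}": "".join(rng.choice(list("ACGT"), size=length))
        for i in range(n_transcripts)
    }
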