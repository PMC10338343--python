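"""Degradome analysis: piRNA prefix groups, absolute quantification,
candidate 3'-cleavage-product identification and the fraction-cleaved
statistic.

Endonucleolytic slicing leaves a 5'-monophosphorylated 3' product, so
5'-monoP RNA species whose 5' end coincides with the t10 position of an
antiparallel piRNA:target duplex are candidate cleavage products.  The
statistic compares, per pairing configuration, the fraction of candidate
sites lost >= 8-fold in piRNA-deficient mutant animals for piRNAs removed
by the mutation (targeted set) against the same fraction for piRNAs still
present (control set, which measures sampling error on short-lived
fragments):

    f_cleaved = f_decreased(targeted) - f_decreased(control)

Uncertainty comes from all 16 single-animal control x mutant pairings
(4 control x 4 mutant degradome replicates) and a bootstrap over candidate
sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .pairing import GuideRNA, PairState, TargetSite, annotate_pairing

AVOGADRO = 6.02214076e23

#: Retention thresholds, all inclusive.
MIN_PREFIX_PPM = 1.0          # >= 1 ppm in every control small-RNA replicate
MAX_MUTANT_PPM = 0.1          # mean mutant abundance <= 0.1 ppm => eliminated
MIN_SPECIES_PPM = 0.04        # degradome species floor (control)
FOLD_THRESHOLD = 8.0          # >= 8-fold loss counts as decreased

#: piRNA intracellular-concentration bin edges (pM), lower-inclusive.
CONCENTRATION_BIN_EDGES = (30.0, 50.0, 100.0, 500.0)
CONCENTRATION_BIN_LABELS = ("<30", "30-50", "50-100", "100-500", ">500")


# ---------------------------------------------------------------------------
# piRNA prefix groups
# ---------------------------------------------------------------------------


def group_pirnas(
    pirnas: pd.DataFrame,
    n_control: int = 12,
    n_mutant: int = 9,
    min_ppm: float = MIN_PREFIX_PPM,
    mutant_max_ppm: float = MAX_MUTANT_PPM,
) -> pd.DataFrame:
    """Filter 25-nt-prefix piRNA groups and partition targeted vs control.

    3' trimming makes piRNA 3' ends heterogeneous, so reads sharing a 25-nt
    5' prefix are one group.  A group is retained if it maps uniquely
    (``unique_mapping``) and is >= ``min_ppm`` in *all* control replicates
    (columns ``control_ppm_1..n``).  Retained groups are ``targeted`` (their
    source locus is deleted in the mutant) when their mean mutant abundance
    (columns ``mutant_ppm_1..m``) is <= ``mutant_max_ppm``.
    """
    ctrl_cols = [f"control_ppm_{i}" for i in range(1, n_control + 1)]
    mut_cols = [f"mutant_ppm_{i}" for i in range(1, n_mutant + 1)]
    for col in ["prefix25", "unique_mapping", *ctrl_cols, *mut_cols]:
        if col not in pirnas.columns:
            raise ValueError(f"piRNA table lacks required column {col!r}")
    retained = (
        pirnas["unique_mapping"].astype(bool)
        & (pirnas[ctrl_cols] >= min_ppm).all(axis=1)
    )
    out = pirnas[retained].copy()
    out["targeted"] = out[mut_cols].mean(axis=1) <= mutant_max_ppm
    return out.reset_index(drop=True)


def absolute_quantify(
    sample_counts: pd.Series,
    spike_counts: pd.Series,
    spike_molecules: pd.Series,
    n_cells: float,
    cell_volume_pL: float = 0.6,
) -> pd.Series:
    """Convert read counts to intracellular molar concentration (pM).

    Spike-in oligos of known molecular input calibrate reads -> molecules by
    a single proportionality constant (total molecules / total spike reads);
    molecules per cell divided by (Avogadro x cell volume) gives molarity.
    The default cell volume of 0.6 pL approximates a primary spermatocyte.
    """
    total_reads = float(spike_counts.sum())
    if total_reads <= 0:
        raise ValueError("zero spike-in recovery: calibration failed")
    molecules_per_read = float(spike_molecules.sum()) / total_reads
    molecules_per_cell = sample_counts * molecules_per_read / n_cells
    molar = molecules_per_cell / (AVOGADRO * cell_volume_pL * 1e-12)
    return molar * 1e12  # mol/L -> pM


# ---------------------------------------------------------------------------
# Candidate cleavage products
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfigurationQuery:
    """A pairing-configuration class, e.g. contiguous g2-g18 or the same
    with one mismatch.

    ``g_start``..``g_end`` must be paired except at ``mismatch_at``
    positions, which must be unpaired; the guide position immediately after
    ``g_end`` must be unpaired (the non-overlap rule that keeps g2-gX
    classes disjoint from g2-g(X+1)).
    """

    g_start: int = 2
    g_end: int = 16
    mismatch_at: tuple = ()

    @property
    def label(self) -> str:
        base = f"g{self.g_start}-g{self.g_end}"
        if self.mismatch_at:
            base += ":mm" + ",".join(str(m) for m in self.mismatch_at)
        return base

    def matches(self, config) -> bool:
        n = len(config)
        if self.g_end >= n:  # need g_end+1 to exist and be unpaired
            return False
        mm = set(self.mismatch_at)
        for i in range(self.g_start, self.g_end + 1):
            paired = config.is_paired(i)
            if i in mm:
                if paired:
                    return False
            elif not paired:
                return False
        if config.is_paired(self.g_end + 1):
            return False
        return True


@dataclass
class CleavageCandidate:
    """A 5'-monoP species explained by >= 1 retained piRNA in one class."""

    species_id: str
    transcript: str
    coordinate: int                      # transcript index of the species 5' end (t10)
    config_label: str
    explaining_pirnas: tuple
    cumulative_abundance_pM: float
    explained_by_targeted: bool
    explained_by_control: bool


def _explains(guide: GuideRNA, transcript_seq: str, cut_coord: int,
              query: ConfigurationQuery, wobble_paired: bool = True):
    """Pairing configuration of guide vs transcript placing t10 at cut_coord,
    or None if the window falls outside the transcript."""
    n = len(guide)
    start = cut_coord + 10 - n   # index of tN
    if start < 0 or start + n > len(transcript_seq):
        return None
    window = TargetSite(sequence=transcript_seq[start : start + n], site_start=0)
    config = annotate_pairing(guide, window, wobble_paired=wobble_paired)
    return config if query.matches(config) else None


def find_candidates(
    species: pd.DataFrame,
    pirna_groups: pd.DataFrame,
    transcripts: Mapping[str, str],
    queries: Sequence[ConfigurationQuery],
    wobble_paired: bool = True,
) -> pd.DataFrame:
    """Identify candidate 3' cleavage products for each configuration class.

    ``species`` rows are 5'-monoP species with columns species_id,
    transcript, coordinate and per-replicate ppm; ``pirna_groups`` carries
    prefix25 sequences, abundance_pM and the targeted flag (from
    :func:`group_pirnas` + :func:`absolute_quantify`).  For each species,
    every retained piRNA whose antiparallel pairing places t10 at the
    species 5' end and satisfies the queried class explains it.  Sites are
    collapsed to a non-redundant list: a site explained by several piRNAs
    is counted once, with the cumulative abundance of all explaining
    piRNAs recorded.
    """
    guides = []
    for _, row in pirna_groups.iterrows():
        guides.append((
            GuideRNA(name=str(row["prefix25"]), sequence=row["prefix25"],
                     abundance_pM=float(row.get("abundance_pM", 0.0) or 0.0)),
            bool(row["targeted"]),
        ))
    rows = []
    skipped = []
    for _, sp in species.iterrows():
        seq = transcripts.get(sp["transcript"])
        if seq is None:
            skipped.append(sp["species_id"])
            continue
        for query in queries:
            explaining = [
                (g, targeted) for g, targeted in guides
                if _explains(g, seq, int(sp["coordinate"]), query, wobble_paired)
            ]
            if not explaining:
                continue
            rows.append({
                "species_id": sp["species_id"],
                "transcript": sp["transcript"],
                "coordinate": int(sp["coordinate"]),
                "config_label": query.label,
                "explaining_pirnas": tuple(g.name for g, _ in explaining),
                "cumulative_abundance_pM": float(
                    sum(g.abundance_pM or 0.0 for g, _ in explaining)
                ),
                "explained_by_targeted": any(t for _, t in explaining),
                "explained_by_control": any(not t for _, t in explaining),
            })
    out = pd.DataFrame(
        rows, columns=[
            "species_id", "transcript", "coordinate", "config_label",
            "explaining_pirnas", "cumulative_abundance_pM",
            "explained_by_targeted", "explained_by_control",
        ],
    )
    out.attrs["skipped_species"] = skipped
    return out


# ---------------------------------------------------------------------------
# Fraction cleaved
# ---------------------------------------------------------------------------


@dataclass
class FractionCleavedResult:
    """f_cleaved for one configuration class.

    ``per_permutation`` holds one f value per control x mutant animal
    pairing (16 for a 4 x 4 cohort); the headline estimate is their median
    and the CI is a percentile bootstrap over candidate sites.
    """

    config_label: str
    f_decreased_targeted: float
    f_decreased_control: float
    f_cleaved: float
    per_permutation: np.ndarray
    ci_low: float
    ci_high: float
    n_targeted_sites: int
    n_control_sites: int


def _decrease_matrix(
    site_species: pd.DataFrame,
    ctrl_cols: Sequence[str],
    mut_cols: Sequence[str],
    fold_threshold: float,
    floor_ppm: float,
) -> np.ndarray:
    """Boolean (n_sites x n_pairings) matrix of the >= fold-threshold rule.

    Zero mutant abundance always counts as decreased; otherwise the fold
    change is control / max(mutant, floor) with a one-read-equivalent floor
    to keep the ratio finite.
    """
    ctrl = site_species[list(ctrl_cols)].to_numpy(float)   # n x 4
    mut = site_species[list(mut_cols)].to_numpy(float)     # n x 4
    n = ctrl.shape[0]
    out = np.empty((n, ctrl.shape[1] * mut.shape[1]), bool)
    k = 0
    for i in range(ctrl.shape[1]):
        for j in range(mut.shape[1]):
            c = ctrl[:, i]
            m = mut[:, j]
            out[:, k] = (m <= 0) | (c / np.maximum(m, floor_ppm) >= fold_threshold)
            k += 1
    return out


def fraction_cleaved(
    candidates: pd.DataFrame,
    species: pd.DataFrame,
    fold_threshold: float = FOLD_THRESHOLD,
    floor_ppm: float = 0.01,
    n_bootstrap: int = 10000,
    seed: Optional[int] = None,
    ctrl_cols: Optional[Sequence[str]] = None,
    mut_cols: Optional[Sequence[str]] = None,
) -> Dict[str, FractionCleavedResult]:
    """The background-subtracted fraction-cleaved statistic per class.

    For each configuration class, non-redundant candidate sites are split
    into a targeted set (explained by >= 1 piRNA eliminated in the mutant)
    and a control set (explained only by piRNAs still present, measuring
    sampling error).  For each of the 16 single-animal pairings the
    decreased fraction is computed in both sets, and

        f_cleaved = f_decreased(targeted) - f_decreased(control)

    per pairing; the headline value is the median over pairings.  The 95%
    CI resamples candidate sites (both sets independently) ``n_bootstrap``
    times, recomputing the median-over-pairings each time.
    """
    if ctrl_cols is None:
        ctrl_cols = [c for c in species.columns if c.startswith("control_ppm_")]
    if mut_cols is None:
        mut_cols = [c for c in species.columns if c.startswith("mutant_ppm_")]
    if not ctrl_cols or not mut_cols:
        raise ValueError("species table lacks control/mutant ppm columns")
    sp = species.set_index("species_id")
    rng = np.random.default_rng(seed)
    results: Dict[str, FractionCleavedResult] = {}
    for label, grp in candidates.groupby("config_label", sort=False):
        # non-redundant site list per set
        sites = grp.drop_duplicates(subset=["transcript", "coordinate"])
        targeted = sites[sites["explained_by_targeted"]]
        control = sites[~sites["explained_by_targeted"]
                        & sites["explained_by_control"]]
        if targeted.empty or control.empty:
            raise ValueError(
                f"{label}: needs nonempty targeted and control candidate sets"
            )
        d_t = _decrease_matrix(sp.loc[targeted["species_id"]], ctrl_cols,
                               mut_cols, fold_threshold, floor_ppm)
        d_c = _decrease_matrix(sp.loc[control["species_id"]], ctrl_cols,
                               mut_cols, fold_threshold, floor_ppm)
        f_t = d_t.mean(axis=0)
        f_c = d_c.mean(axis=0)
        per_perm = f_t - f_c
        boot = np.empty(n_bootstrap)
        nt, nc = d_t.shape[0], d_c.shape[0]
        chunk = max(1, int(2e6 // max(nt + nc, 1)))
        done = 0
        while done < n_bootstrap:
            b = min(chunk, n_bootstrap - done)
            idx_t = rng.integers(0, nt, size=(b, nt))
            idx_c = rng.integers(0, nc, size=(b, nc))
            ft = d_t[idx_t].mean(axis=1)        # (b, 16)
            fc = d_c[idx_c].mean(axis=1)
            boot[done : done + b] = np.median(ft - fc, axis=1)
            done += b
        results[label] = FractionCleavedResult(
            config_label=label,
            f_decreased_targeted=float(np.median(f_t)),
            f_decreased_control=float(np.median(f_c)),
            f_cleaved=float(np.median(per_perm)),
            per_permutation=per_perm,
            ci_low=float(np.percentile(boot, 2.5)),
            ci_high=float(np.percentile(boot, 97.5)),
            n_targeted_sites=int(nt),
            n_control_sites=int(nc),
        )
    return results


def bin_by_concentration(
    candidates: pd.DataFrame,
    species: pd.DataFrame,
    edges: Sequence[float] = CONCENTRATION_BIN_EDGES,
    labels: Sequence[str] = CONCENTRATION_BIN_LABELS,
    **fc_kwargs,
) -> Dict[str, Dict[str, FractionCleavedResult]]:
    """Recompute f_cleaved within piRNA-concentration bins.

    Sites are partitioned by the cumulative abundance (pM) of all piRNAs
    explaining them; bins are lower-inclusive (a site at exactly 30 pM is
    in '30-50').  Returns {bin_label: {config_label: result}}; bins whose
    targeted or control set is empty are omitted.
    """
    bounds = [-math.inf, *edges, math.inf]
    out: Dict[str, Dict[str, FractionCleavedResult]] = {}
    for lo, hi, lab in zip(bounds[:-1], bounds[1:], labels):
        mask = (candidates["cumulative_abundance_pM"] >= lo) & (
            candidates["cumulative_abundance_pM"] < hi
        )
        sub = candidates[mask]
        if sub.empty:
            continue
        try:
            out[lab] = fraction_cleaved(sub, species, **fc_kwargs)
        except ValueError:
            continue
    return out
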