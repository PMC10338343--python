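"""Cleave-'n-Seq analysis: depletion normalization, burst-kinetics fitting,
mismatch fold-change summaries, and cut-site mapping from 3' products.

The experiment incubates piRISC + GTSF1 with a library of 30-nt target
variants under single-turnover conditions and sequences the *uncleaved*
RNA remaining at each timepoint (0, 1, 2, 4, 8 min and 0, 20, 60, 120,
240, 480, 960 min; three trials of each subset).  Per-variant depletion is
converted to relative cleaved product and fit to the burst-and-steady-state
scheme E + S <-> ES --k2--> EP --k3--> E + P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .pairing import PairingConfiguration

#: Timepoints (minutes) of the fast and slow sampling subsets.
FAST_TIMEPOINTS_MIN = (0.0, 1.0, 2.0, 4.0, 8.0)
SLOW_TIMEPOINTS_MIN = (0.0, 20.0, 60.0, 120.0, 240.0, 480.0, 960.0)

#: Parameter bounds of the burst fit: amplitude (fraction of cleavable
#: substrate), chemistry rate k2 (1/min), and product-release rate k3
#: (1/min; the tight bound asserts the single-turnover regime).
E_REL_BOUNDS = (0.5, 1.0)
K2_BOUNDS = (0.0, 100.0)
K3_BOUNDS = (0.0, 1e-4)

MAX_FUNCTION_EVALS = 10000


@dataclass(frozen=True)
class TargetLibraryEntry:
    """One 30-nt target variant of the cleavage library."""

    variant_id: str
    sequence: str
    configuration: PairingConfiguration
    barcode: Optional[str] = None


# ---------------------------------------------------------------------------
# Normalization and relative product
# ---------------------------------------------------------------------------


def normalize_library(
    counts: pd.DataFrame,
    normalizer_ids: Sequence[str],
) -> pd.DataFrame:
    """Depth- and depletion-normalize a variant x sample count table.

    Each column is scaled to parts per million, then divided by the summed
    ppm of the normalizer variants (targets with <= 7-nt complementarity to
    the guide, which are not cleaved and so track overall library recovery).
    """
    normalizer_ids = list(normalizer_ids)
    if not normalizer_ids:
        raise ValueError("normalizer set is empty")
    missing = set(normalizer_ids) - set(counts.index)
    if missing:
        raise ValueError(f"normalizer variants absent from table: {sorted(missing)}")
    ppm = counts / counts.sum(axis=0) * 1e6
    norm_sum = ppm.loc[normalizer_ids].sum(axis=0)
    if (norm_sum <= 0).any():
        raise ValueError("normalizer variants have zero counts in some sample")
    return ppm / norm_sum


def compute_p_relative(normalized: pd.DataFrame) -> pd.DataFrame:
    """Relative cleaved product per variant, trial and nonzero timepoint.

    ``normalized`` must have MultiIndex columns (trial, time_min) including
    time 0 for every trial.  P_relative = (v_0 - v_t) / v_0; negative values
    (counting noise on uncleaved variants) are retained so least-squares
    fitting sees symmetric noise.  Variants with zero time-0 abundance in
    any trial are dropped and listed in ``attrs['unquantifiable']``.
    """
    if not isinstance(normalized.columns, pd.MultiIndex):
        raise ValueError("expected MultiIndex columns (trial, time_min)")
    trials = sorted({t for t, _ in normalized.columns})
    rows = []
    bad: set = set()
    for trial in trials:
        sub = normalized[trial]
        if 0.0 not in sub.columns:
            raise ValueError(f"trial {trial!r} lacks a time-0 sample")
        v0 = sub[0.0]
        bad |= set(sub.index[v0 <= 0])
        for t in sub.columns:
            if t == 0.0:
                continue
            p = (v0 - sub[t]) / v0
            rows.append(pd.DataFrame({
                "variant_id": sub.index,
                "trial": trial,
                "time_min": t,
                "p_relative": p.to_numpy(),
            }))
    out = pd.concat(rows, ignore_index=True)
    out = out[~out["variant_id"].isin(bad)].reset_index(drop=True)
    out.attrs["unquantifiable"] = sorted(bad)
    return out


# ---------------------------------------------------------------------------
# Burst-and-steady-state fit
# ---------------------------------------------------------------------------


def burst_model(t, e_rel, k2, k3):
    """Single-turnover burst equation.

    P_relative(t) = E_rel * ((k2/(k2+k3))^2 (1 - exp(-(k2+k3) t))
                             + k2 k3 / (k2+k3) * t)

    The amplitude is applied once: a squared amplitude would push the burst
    phase above the cleavable fraction, violating P <= E.
    """
    t = np.asarray(t, float)
    ksum = k2 + k3
    if ksum <= 0:
        return np.zeros_like(t)
    burst = (k2 / ksum) ** 2 * (1.0 - np.exp(-ksum * t))
    steady = (k2 * k3 / ksum) * t
    return e_rel * (burst + steady)


@dataclass
class RateFit:
    """Burst-and-steady-state fit for one target variant.

    ``k = k2 + k3`` is the pre-steady-state cleavage rate.  Standard
    deviations come from the fit covariance.  ``flags`` lists diagnostics:
    'null_signal', 'fast_phase_unidentifiable', 'pinned_k2_bounds',
    'fit_failed'.
    """

    e_relative: float
    k2: float
    k3: float
    e_relative_sd: float = float("nan")
    k2_sd: float = float("nan")
    k3_sd: float = float("nan")
    flags: tuple = ()

    @property
    def k(self) -> float:
        return self.k2 + self.k3

    @property
    def k_sd(self) -> float:
        return math.hypot(self.k2_sd, self.k3_sd)


def fit_burst(times_min: Sequence[float], p_relative: Sequence[float]) -> RateFit:
    """Bounded trust-region least-squares fit of pooled P_relative data.

    Pools all trials/timepoints as independent observations.  Requires at
    least 4 distinct nonzero timepoints.  Multi-start over a small grid of
    k2 initializations; at most 10,000 function evaluations per start.
    """
    t = np.asarray(times_min, float)
    p = np.asarray(p_relative, float)
    mask = np.isfinite(t) & np.isfinite(p) & (t > 0)
    t, p = t[mask], p[mask]
    distinct = np.unique(t)
    if distinct.size < 4:
        raise ValueError("need >= 4 distinct nonzero timepoints")

    flags: List[str] = []
    if np.max(p) < 0.02:
        return RateFit(e_relative=float("nan"), k2=0.0, k3=0.0,
                       flags=("null_signal",))

    lb = [E_REL_BOUNDS[0], K2_BOUNDS[0], K3_BOUNDS[0]]
    ub = [E_REL_BOUNDS[1], K2_BOUNDS[1], K3_BOUNDS[1]]
    k2_starts = {1.0 / tm for tm in (distinct.min(), np.median(distinct), distinct.max())}
    k2_starts.add(0.01)
    best = None
    for k2_0 in sorted(k2_starts):
        p0 = [0.9, min(max(k2_0, 1e-6), 99.0), 1e-6]
        try:
            popt, pcov = optimize.curve_fit(
                burst_model, t, p, p0=p0, bounds=(lb, ub),
                method="trf", maxfev=MAX_FUNCTION_EVALS,
            )
        except RuntimeError:
            continue
        ssr = float(np.sum((burst_model(t, *popt) - p) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)
    if best is None:
        return RateFit(e_relative=float("nan"), k2=float("nan"), k3=float("nan"),
                       flags=("fit_failed",))
    _, popt, pcov = best
    e_rel, k2, k3 = popt
    sds = np.sqrt(np.maximum(np.diag(pcov), 0.0))

    # Saturation probe: if even the earliest sampled timepoint is already at
    # the burst plateau, only a lower bound on k2 is identified.
    ksum = k2 + k3
    if ksum * distinct.min() > 3.0 and burst_model(distinct.min(), *popt) > 0.95 * e_rel:
        flags.append("fast_phase_unidentifiable")
    if k2 >= K2_BOUNDS[1] * (1 - 1e-6):
        flags.append("pinned_k2_bounds")
    return RateFit(
        e_relative=float(e_rel), k2=float(k2), k3=float(k3),
        e_relative_sd=float(sds[0]), k2_sd=float(sds[1]), k3_sd=float(sds[2]),
        flags=tuple(flags),
    )


def fit_burst_table(p_rel: pd.DataFrame) -> pd.DataFrame:
    """Fit every variant in a tidy P_relative table.

    ``p_rel`` has columns variant_id, trial, time_min, p_relative (as
    produced by :func:`compute_p_relative`).  Returns one row per variant
    with the fitted parameters, k = k2 + k3, and flags.
    """
    rows = []
    for vid, grp in p_rel.groupby("variant_id", sort=False):
        fit = fit_burst(grp["time_min"], grp["p_relative"])
        rows.append({
            "variant_id": vid,
            "e_relative": fit.e_relative,
            "k2": fit.k2, "k3": fit.k3, "k": fit.k,
            "e_relative_sd": fit.e_relative_sd,
            "k2_sd": fit.k2_sd, "k3_sd": fit.k3_sd,
            "k_sd": fit.k_sd,
            "flags": ";".join(fit.flags),
        })
    return pd.DataFrame(rows).set_index("variant_id")


# ---------------------------------------------------------------------------
# Fold-change summaries
# ---------------------------------------------------------------------------


def fold_change_summary(
    fits: pd.DataFrame,
    manifest: pd.DataFrame,
    grouping: Sequence[str],
    perfect_flag: str = "is_perfect",
) -> pd.DataFrame:
    """Median and IQR of k(perfect) / k(variant) per grouping.

    ``manifest`` is indexed by variant_id and must carry the grouping
    columns plus a boolean ``is_perfect`` marking the perfectly paired
    reference variant of each (guide, protein) run; reference matching uses
    any grouping columns named 'guide' or 'protein' that are present.
    """
    df = manifest.join(fits[["k"]], how="inner")
    ref_cols = [c for c in ("guide", "protein") if c in df.columns]
    perfect = df[df[perfect_flag].astype(bool)]
    if perfect.empty:
        raise ValueError("no perfect-match reference variant in manifest")
    if ref_cols:
        ref_k = perfect.groupby(ref_cols)["k"].median()
        df = df.join(ref_k.rename("k_perfect"), on=ref_cols)
    else:
        df = df.assign(k_perfect=perfect["k"].median())
    if df["k_perfect"].isna().any():
        raise ValueError("missing perfect reference for some groups")
    df = df[~df[perfect_flag].astype(bool)].copy()
    df["fold_change"] = df["k_perfect"] / df["k"]
    g = df.groupby(list(grouping))["fold_change"]
    out = g.agg(
        median="median",
        q1=lambda s: s.quantile(0.25),
        q3=lambda s: s.quantile(0.75),
        n="size",
    )
    return out


# ---------------------------------------------------------------------------
# Cut-site mapping from sequenced 3' products
# ---------------------------------------------------------------------------


@dataclass
class CutSiteReport:
    """Inferred cleavage positions for one variant (or spiked control)."""

    variant_id: str
    offsets: Dict[int, int]            # product-5'-end offset from t10 -> reads
    n_unmapped: int
    is_control: bool = False

    @property
    def n_mapped(self) -> int:
        return sum(self.offsets.values())

    @property
    def fraction_canonical(self) -> float:
        n = self.n_mapped
        return self.offsets.get(0, 0) / n if n else float("nan")


def map_cut_sites(
    product_reads: Iterable[Tuple[str, str]],
    library: pd.DataFrame,
) -> Dict[str, CutSiteReport]:
    """Map 3'-cleavage-product reads to per-variant cut-position histograms.

    ``product_reads`` yields (barcode, read_sequence) pairs; ``library`` is
    indexed by barcode with columns variant_id, sequence, t10_index and an
    optional boolean is_control for the spiked 5'-monophosphorylated
    control oligos (whose t10_index is their own 5' end, so self-mapping
    reads report offset 0).  A read's 5' end is located in the variant by
    exact prefix search; the offset is (found index - t10_index).
    """
    if library.index.duplicated().any():
        dupes = library.index[library.index.duplicated()].unique().tolist()
        raise ValueError(f"barcode collision in library manifest: {dupes}")
    reports: Dict[str, CutSiteReport] = {}
    for _, row in library.iterrows():
        reports[row["variant_id"]] = CutSiteReport(
            variant_id=row["variant_id"], offsets={}, n_unmapped=0,
            is_control=bool(row.get("is_control", False)),
        )
    by_barcode = library.to_dict("index")
    for barcode, read in product_reads:
        entry = by_barcode.get(barcode)
        if entry is None:
            continue
        rep = reports[entry["variant_id"]]
        seq = entry["sequence"]
        probe = read[: min(len(read), 12)]
        pos = seq.find(probe)
        if pos == -1 or seq.find(probe, pos + 1) != -1:
            rep.n_unmapped += 1
            continue
        off = pos - int(entry["t10_index"])
        rep.offsets[off] = rep.offsets.get(off, 0) + 1
    return reports
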