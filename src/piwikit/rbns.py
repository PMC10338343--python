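"""Bind-'n-Seq analysis: site assignment and equilibrium K_d estimation.

The binding experiment incubates a 20-nt random-sequence RNA library
(100 nM) with a concentration series of active piRISC (0.003-1 nM) and
sequences the bound fraction.  Reads are partitioned into non-overlapping
site types (contiguous complementarity windows plus the canonical 8-mer
seed site and a no-site class), and per-site dissociation constants are
estimated by maximum likelihood under an equilibrium competition model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pairing import GuideRNA, as_rna, complement, reverse_complement

NO_SITE = "no_site"
REJECT = "REJECT"
SEED_8MER = "8mer"

#: Active-piRISC concentration series (nM) used in the binding reactions.
DEFAULT_CONCENTRATIONS_NM = (0.003, 0.01, 0.032, 0.1, 0.316, 1.0)

#: Total RNA library concentration in the binding reaction (nM).
DEFAULT_LIBRARY_NM = 100.0

#: Grid of initial guesses for stock piRISC concentration and the no-site
#: K_d (nM); the 7 x 7 grid gives the 49 optimizer starts.
INITIAL_GUESS_GRID_NM = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0)

READ_PREFIX = "GAUC"
READ_SUFFIX = "UGGA"
RANDOM_REGION_LEN = 20


@dataclass(frozen=True)
class SiteWindow:
    """Contiguous complementarity window g_start..g_end (1-based, inclusive)."""

    g_start: int
    g_end: int

    @property
    def label(self) -> str:
        return f"g{self.g_start}-g{self.g_end}"

    def __len__(self) -> int:
        return self.g_end - self.g_start + 1


@dataclass
class SiteCatalog:
    """Site types interrogated in every read.

    Windows of length <= 10 require non-complementary flanking target
    nucleotides on both sides; 11-nt windows require a non-complementary
    flank only opposite the guide position 5' of the window; windows >= 12 nt
    need no flanks.  The special 8-mer site is seed pairing (g2-g8) plus an
    adenosine at t1, regardless of g1 identity.
    """

    guide: GuideRNA
    windows: List[SiteWindow]
    include_seed_8mer: bool = True

    def __post_init__(self) -> None:
        n = len(self.guide)
        for w in self.windows:
            if not (1 <= w.g_start <= w.g_end <= n):
                raise ValueError(f"window {w.label} outside guide of length {n}")

    @property
    def site_labels(self) -> List[str]:
        labels = [w.label for w in self.windows]
        if self.include_seed_8mer:
            labels.append(SEED_8MER)
        return labels

    def motif(self, window: SiteWindow) -> str:
        """Target motif 5'->3' (reads t_end .. t_start)."""
        g = self.guide.sequence
        return reverse_complement(g[window.g_start - 1 : window.g_end])

    def seed_8mer_motif(self) -> str:
        """t8..t2 complement followed by t1A."""
        g = self.guide.sequence
        return reverse_complement(g[1:8]) + "A"


def default_catalog(guide: GuideRNA, min_len: int = 7, max_len: int = 11,
                    include_seed_8mer: bool = True) -> SiteCatalog:
    """Catalog of g2-anchored windows g2-g(2+min_len-1) .. g2-g(2+max_len-1)."""
    windows = [SiteWindow(2, 1 + L) for L in range(min_len, max_len + 1)]
    return SiteCatalog(guide=guide, windows=windows,
                       include_seed_8mer=include_seed_8mer)


def _occurrences(read: str, catalog: SiteCatalog) -> List[Tuple[str, int, int]]:
    """All valid (label, start, end) motif occurrences in a read."""
    g = catalog.guide.sequence
    n = len(g)
    found: List[Tuple[str, int, int]] = []

    def flank_mismatches(pos: int, g_index: int) -> bool:
        """True if read[pos] exists and is NOT the WC partner of g_index."""
        if pos < 0 or pos >= len(read):
            return False
        if g_index < 1 or g_index > n:
            return True  # no such guide position: nothing to pair with
        return read[pos] != complement(g[g_index - 1])

    for w in catalog.windows:
        motif = catalog.motif(w)
        L = len(motif)
        start = read.find(motif)
        while start != -1:
            ok = True
            if L <= 10:
                # 5' flank of the motif opposes g_(end+1); 3' flank opposes
                # g_(start-1).  Both must be non-complementary.
                ok = flank_mismatches(start - 1, w.g_end + 1) and \
                    flank_mismatches(start + L, w.g_start - 1)
            elif L == 11:
                ok = flank_mismatches(start + L, w.g_start - 1)
            if ok:
                found.append((w.label, start, start + L))
            start = read.find(motif, start + 1)

    if catalog.include_seed_8mer:
        motif = catalog.seed_8mer_motif()
        L = len(motif)
        start = read.find(motif)
        while start != -1:
            if flank_mismatches(start - 1, 9):  # t9 must not pair g9
                found.append((SEED_8MER, start, start + L))
            start = read.find(motif, start + 1)

    # The seed window g2-g8 and the 8-mer overlap by construction whenever
    # t1 is A; keep only the 8-mer in that case so the classes stay disjoint.
    eights = [f for f in found if f[0] == SEED_8MER]
    if eights:
        found = [
            f for f in found
            if f[0] != "g2-g8"
            or not any(e[1] == f[1] for e in eights)
        ]
    return found


def assign_site(read: str, catalog: SiteCatalog) -> str:
    """Assign one read to a site type, ``no_site``, or ``REJECT``.

    The read must follow the library layout: 4-nt constant prefix, 20-nt
    random region, 4-nt constant suffix.  The whole 28-nt window (constant
    flanks included) is searched.  Reads containing more than one motif
    occurrence, including partially overlapping ones, are rejected.
    """
    read = as_rna(read)
    if len(read) != len(READ_PREFIX) + RANDOM_REGION_LEN + len(READ_SUFFIX):
        raise ValueError(f"read length {len(read)} != 28")
    if not (read.startswith(READ_PREFIX) and read.endswith(READ_SUFFIX)):
        raise ValueError("read does not match GAUC + N20 + UGGA layout")
    occ = _occurrences(read, catalog)
    if not occ:
        return NO_SITE
    if len(occ) > 1:
        return REJECT
    return occ[0][0]


def count_sites(reads: Iterable[str], catalog: SiteCatalog) -> pd.Series:
    """Tally assignments over a read set (REJECTed reads are dropped)."""
    labels = catalog.site_labels + [NO_SITE]
    counts = {lab: 0 for lab in labels}
    n_reject = 0
    for r in reads:
        lab = assign_site(r, catalog)
        if lab == REJECT:
            n_reject += 1
        else:
            counts[lab] += 1
    s = pd.Series(counts, name="count")
    s.attrs["n_rejected"] = n_reject
    return s


# ---------------------------------------------------------------------------
# Equilibrium binding model MLE
# ---------------------------------------------------------------------------


@dataclass
class SiteCountTable:
    """Site-type x sample count matrix for one guide/protein experiment.

    ``counts`` has one row per site type (including ``no_site``) and one
    column per sample; the input column is named ``input`` and the bound
    columns are ordered to match ``concentrations_nM``.
    """

    counts: pd.DataFrame
    concentrations_nM: Sequence[float] = DEFAULT_CONCENTRATIONS_NM
    library_nM: float = DEFAULT_LIBRARY_NM

    def __post_init__(self) -> None:
        if "input" not in self.counts.columns:
            raise ValueError("count table must contain an 'input' column")
        bound_cols = [c for c in self.counts.columns if c != "input"]
        if len(bound_cols) != len(self.concentrations_nM):
            raise ValueError(
                f"{len(bound_cols)} bound columns but "
                f"{len(self.concentrations_nM)} concentrations"
            )
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        self.bound_columns = bound_cols

    @property
    def site_types(self) -> List[str]:
        return list(self.counts.index)


@dataclass
class KdEstimate:
    """Median-of-starts dissociation constant for one site type."""

    site_type: str
    kd_pM: float
    start_estimates_pM: np.ndarray
    n_starts_converged: int
    flagged: bool = False


def _free_risc(e_total: float, s_sites: np.ndarray, kds: np.ndarray,
               rtol: float = 1e-13, max_iter: int = 200) -> float:
    """Solve E_free from total-RISC conservation by bisection.

    E_total = E_free + sum_i S_i * E_free / (E_free + Kd_i); the left side
    is monotone in E_free so the root is bracketed by [0, E_total].
    """
    if e_total <= 0:
        return 0.0
    lo, hi = 0.0, e_total
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        bound = np.sum(s_sites * mid / (mid + kds))
        if mid + bound > e_total:
            hi = mid
        else:
            lo = mid
        if hi - lo <= rtol * max(hi, 1e-30):
            break
    return 0.5 * (lo + hi)


def _nll(params: np.ndarray, log_f_obs: np.ndarray, ns_idx: int,
         input_counts: np.ndarray, bound_counts: np.ndarray,
         dilution: np.ndarray, library_nM: float) -> float:
    """Joint negative log-likelihood of input and bound samples.

    Parameters are log10 K_d per site type (nM), log10 stock concentration
    (nM at the top dilution), and log-frequency adjustments for every site
    type except the no-site reference (softmax-normalized around the
    observed input frequencies).  Treating the library composition as free
    parameters informed by *both* the input and the bound samples removes
    the bias that plugging in noisy input frequencies would create for
    strongly enriched sites.
    """
    m = len(log_f_obs)
    kds = 10.0 ** params[:m]
    stock = 10.0 ** params[m]
    c = log_f_obs.copy()
    c[np.arange(m) != ns_idx] += params[m + 1 :]
    e = np.exp(c - c.max())
    f = e / e.sum()
    s_sites = f * library_nM
    nll = -float(np.sum(input_counts * np.log(np.maximum(f, 1e-300))))
    for j in range(len(dilution)):
        e_free = _free_risc(stock * dilution[j], s_sites, kds)
        theta = e_free / (e_free + kds)
        p = f * theta
        tot = p.sum()
        if tot <= 0 or not np.isfinite(tot):
            return 1e12
        p = p / tot
        nll -= float(np.sum(bound_counts[:, j] * np.log(np.maximum(p, 1e-300))))
    return nll


def fit_kd_mle(
    table: SiteCountTable,
    initial_guesses_nM: Sequence[float] = INITIAL_GUESS_GRID_NM,
    exclude_long_sites_nt: int = 15,
) -> Dict[str, KdEstimate]:
    """Maximum-likelihood K_d per site type across the concentration series.

    The optimizer runs from every combination of the 7 stock-concentration
    guesses and 7 no-site K_d guesses (49 starts); the median of the 49
    per-start estimates is reported for each site.  Sites long enough to be
    sliced (>= ``exclude_long_sites_nt``, parsed from ``gA-gB`` labels) are
    excluded, as are sites absent from the input sample.

    Bounded L-BFGS-B in log10-K_d space; an estimate is flagged when more
    than half of the starts fail to converge or pin at the box bounds.
    """
    counts = table.counts
    keep = []
    for site in counts.index:
        if counts.loc[site, "input"] <= 0:
            continue
        if site not in (NO_SITE, SEED_8MER) and "-g" in site:
            g_start, g_end = site.lstrip("g").split("-g")
            if int(g_end) - int(g_start) + 1 >= exclude_long_sites_nt:
                continue
        keep.append(site)
    if NO_SITE not in keep:
        raise ValueError("count table must retain a no_site row with input reads")

    sub = counts.loc[keep]
    input_counts = sub["input"].to_numpy(float)
    input_freq = input_counts / input_counts.sum()
    log_f_obs = np.log(input_freq)
    bound = sub[table.bound_columns].to_numpy(float)
    conc = np.asarray(table.concentrations_nM, float)
    dilution = conc / conc.max()

    ns_idx = keep.index(NO_SITE)
    m = len(keep)
    lo = np.concatenate([np.full(m + 1, -6.0), np.full(m - 1, -8.0)])
    hi = np.concatenate([np.full(m + 1, 4.0), np.full(m - 1, 8.0)])
    bounds = list(zip(lo, hi))

    # Moment-style seeding of enriched-site Kd from top-sample enrichment
    # relative to the no-site class.
    with np.errstate(divide="ignore", invalid="ignore"):
        enrich = (bound[:, -1] / bound[:, -1].sum()) / input_freq
        rel = enrich / max(enrich[ns_idx], 1e-12)
        rel = np.clip(np.nan_to_num(rel, nan=1.0, posinf=1e6), 1e-3, 1e6)

    results = np.full((len(initial_guesses_nM) ** 2, m), np.nan)
    converged = np.zeros(results.shape[0], bool)
    run = 0
    for stock0 in initial_guesses_nM:
        for kd_ns0 in initial_guesses_nM:
            x0 = np.zeros(2 * m)
            x0[:m] = np.log10(np.clip(kd_ns0 / rel, 1e-6, 1e4))
            x0[ns_idx] = math.log10(kd_ns0)
            x0[m] = math.log10(stock0)
            res = optimize.minimize(
                _nll, x0,
                args=(log_f_obs, ns_idx, input_counts, bound, dilution,
                      table.library_nM),
                method="L-BFGS-B", bounds=bounds,
                # the objective is computed through an inner root solve, so
                # finite-difference steps must stay well above its tolerance
                options={"maxiter": 2000, "eps": 1e-5},
            )
            results[run] = 10.0 ** res.x[:m]
            at_bound = np.any(
                (res.x[:m] <= lo[:m] + 1e-6) | (res.x[:m] >= hi[:m] - 1e-6)
            )
            converged[run] = bool(res.success) and not at_bound
            run += 1

    out: Dict[str, KdEstimate] = {}
    n_conv = int(converged.sum())
    flagged = n_conv < results.shape[0] / 2
    for i, site in enumerate(keep):
        est = results[:, i] * 1e3  # nM -> pM
        out[site] = KdEstimate(
            site_type=site,
            kd_pM=float(np.median(est)),
            start_estimates_pM=est,
            n_starts_converged=n_conv,
            flagged=flagged,
        )
    return out


# ---------------------------------------------------------------------------
# Double-filter binding fit and energy regression
# ---------------------------------------------------------------------------


def filter_binding_fraction(e_total: np.ndarray, kd: float, s_total: float) -> np.ndarray:
    """Closed-form fraction of target bound under total-concentration binding.

    f = ((E_T + S_T + Kd) - sqrt((E_T + S_T + Kd)^2 - 4 E_T S_T)) / (2 S_T)
    """
    e = np.asarray(e_total, float)
    b = e + s_total + kd
    disc = np.maximum(b * b - 4.0 * e * s_total, 0.0)
    return (b - np.sqrt(disc)) / (2.0 * s_total)


@dataclass
class FilterBindingFit:
    kd: float
    kd_sd: float
    flagged: bool


def fit_filter_binding(e_total: Sequence[float], fraction_bound: Sequence[float],
                       s_total: float) -> FilterBindingFit:
    """Least-squares fit of the quadratic binding solution; returns K_d.

    Flat curves (no transition across the titration) are unidentifiable and
    flagged rather than fit.
    """
    e = np.asarray(e_total, float)
    f = np.asarray(fraction_bound, float)
    if np.any((f < -0.05) | (f > 1.05)):
        raise ValueError("fraction bound must lie in [0, 1]")
    if f.max() - f.min() < 0.05:
        return FilterBindingFit(kd=float("nan"), kd_sd=float("nan"), flagged=True)

    def model(e_t, log10_kd):
        return filter_binding_fraction(e_t, 10.0 ** log10_kd, s_total)

    p0 = [math.log10(max(np.median(e), 1e-12))]
    popt, pcov = optimize.curve_fit(model, e, f, p0=p0, maxfev=10000)
    kd = 10.0 ** popt[0]
    kd_sd = kd * math.log(10) * math.sqrt(max(pcov[0, 0], 0.0))
    return FilterBindingFit(kd=float(kd), kd_sd=float(kd_sd), flagged=False)


def energy_regression(
    measured_energies: Sequence[float],
    predicted_energies: Sequence[float],
    n_permutations: int = 10000,
    seed: Optional[int] = None,
) -> Tuple[float, float]:
    """OLS r^2 plus a two-tailed permutation P for Pearson's correlation.

    The permutation null shuffles the pairing of the two columns; the P
    value uses the add-one convention P = (1 + #{|r*| >= |r|}) / (B + 1).
    """
    x = np.asarray(predicted_energies, float)
    y = np.asarray(measured_energies, float)
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant column: correlation undefined")
    r, _ = stats.pearsonr(x, y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        r_perm, _ = stats.pearsonr(x, rng.permutation(y))
        if abs(r_perm) >= abs(r) - 1e-12:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return float(r * r), float(p)
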