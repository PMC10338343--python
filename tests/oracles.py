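"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's implementation paths: they rescan
sequences character by character with locally defined pairing tables.
"""

from typing import List, Tuple

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WC = {"AU", "UA", "GC", "CG"}
_WOBBLE = {"GU", "UG"}


def oracle_assign_site(read: str, guide: str, windows: List[Tuple[int, int]],
                       include_8mer: bool = True) -> str:
    """Sliding-window site assignment with flank rules, char by char.

    windows are (g_start, g_end) 1-based inclusive.  Returns the site
    label, 'no_site', or 'REJECT' (more than one motif occurrence).
    """
    hits = []  # (label, read_start, read_end)

    def pairs_wc(read_pos: int, g_pos: int) -> bool:
        if read_pos < 0 or read_pos >= len(read) or not 1 <= g_pos <= len(guide):
            return False
        return read[read_pos] == _COMP[guide[g_pos - 1]]

    for g_start, g_end in windows:
        L = g_end - g_start + 1
        for p in range(0, len(read) - L + 1):
            # motif runs t_end .. t_start: read[p + j] opposes g_(end - j)
            if not all(pairs_wc(p + j, g_end - j) for j in range(L)):
                continue
            if L <= 10:
                # flanks on both sides must NOT pair (absent guide position
                # counts as satisfied, absent read position as violated)
                left_ok = (
                    g_end + 1 > len(guide)
                    or (0 <= p - 1 and not pairs_wc(p - 1, g_end + 1))
                )
                right_ok = (
                    g_start - 1 < 1
                    or (p + L < len(read) and not pairs_wc(p + L, g_start - 1))
                )
                if not (left_ok and right_ok):
                    continue
            elif L == 11:
                if not (g_start - 1 < 1
                        or (p + L < len(read)
                            and not pairs_wc(p + L, g_start - 1))):
                    continue
            hits.append((f"g{g_start}-g{g_end}", p, p + L))

    if include_8mer:
        L = 8
        for p in range(0, len(read) - L + 1):
            if read[p + 7] != "A":
                continue
            if not all(pairs_wc(p + j, 8 - j) for j in range(7)):
                continue
            if 0 <= p - 1 and not pairs_wc(p - 1, 9):
                hits.append(("8mer", p, p + L))
        eight_starts = {h[1] for h in hits if h[0] == "8mer"}
        hits = [h for h in hits
                if h[0] != "g2-g8" or h[1] not in eight_starts]

    if not hits:
        return "no_site"
    if len(hits) > 1:
        return "REJECT"
    return hits[0][0]


def oracle_pair_states(guide: str, window: str) -> List[str]:
    """Per-position states WC/GU/MM; window runs tN..t1 5'->3'."""
    n = len(guide)
    out = []
    for i in range(1, n + 1):
        pair = guide[i - 1] + window[n - i]
        out.append("WC" if pair in _WC else "GU" if pair in _WOBBLE else "MM")
    return out


def oracle_competence(guide_rna: str, sense_window: str) -> Tuple[bool, bool]:
    """(piRNA competent, siRNA competent) per positional mismatch rules.

    ``sense_window`` is the transposon sense strand covered by the guide,
    leftmost position opposing g26.  Wobbles count as mismatches.
    """
    g = guide_rna.replace("T", "U")
    s = sense_window.replace("U", "T")
    n = len(g)
    assert n == 26 and len(s) == 26
    dna_comp = {"A": "T", "C": "G", "G": "C", "U": "A"}
    mism = []
    for i in range(1, n + 1):
        sense_base = s[n - i]
        mism.append(sense_base != dna_comp[g[i - 1]])
    total = sum(mism)
    pi_ok = total <= 6
    first21 = mism[:21]
    seed = sum(mism[1:8])           # g2..g8
    critical = any(mism[p - 1] for p in (9, 10, 11, 13))
    si_ok = sum(first21) <= 5 and seed <= 1 and not critical
    return pi_ok, si_ok


def oracle_pr_auc(labels, scores) -> float:
    """Threshold-enumerating trapezoidal PR integration."""
    pairs = sorted(zip(scores, labels), key=lambda x: -x[0])
    n_pos = sum(labels)
    thresholds = sorted({s for s, _ in pairs}, reverse=True)
    points = [(0.0, None)]
    recalls, precisions = [0.0], []
    for th in thresholds:
        tp = sum(1 for s, l in pairs if s >= th and l == 1)
        fp = sum(1 for s, l in pairs if s >= th and l == 0)
        recalls.append(tp / n_pos)
        precisions.append(tp / (tp + fp))
    precisions = [precisions[0]] + precisions
    auc = 0.0
    for i in range(1, len(recalls)):
        auc += (recalls[i] - recalls[i - 1]) * (
            precisions[i] + precisions[i - 1]
        ) / 2.0
    return auc


def oracle_shared_fraction(transcripts, consensus, k) -> float:
    """Quadratic-time substring search for shared k-mers."""
    n_hit = 0
    cons = [c.upper().replace("U", "T") for c in consensus]
    for tx in transcripts:
        tx = tx.upper().replace("U", "T")
        hit = False
        for i in range(len(tx) - k + 1):
            sub = tx[i : i + k]
            if any(sub in c for c in cons):
                hit = True
                break
        if hit:
            n_hit += 1
    return n_hit / len(transcripts)
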