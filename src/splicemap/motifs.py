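"""Discriminative motif discovery and positional RNA maps.

Discovery follows the DREME recipe: enumerate every exact word (default
widths 4-8) occurring in the positive set, rank candidates by a one-sided
Fisher exact test on sequence-level presence against the negative set,
greedily generalize the best core one position at a time to IUPAC classes
while the p-value improves, report the motif, erase its matches from the
positive sequences and repeat.  Matching is sense-strand only (RBP motifs
act on the pre-mRNA) and overlapping occurrences count.

Positional profiles map match centers onto a meta-exon axis: 250 absolute
upstream-intron positions anchored at the 3' splice site, the exon scaled to
a fixed number of bins, and 250 absolute downstream-intron positions
anchored at the 5' splice site.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_SET_TO_CODE = {frozenset(v): k for k, v in IUPAC.items()}


def iupac_regex(word: str) -> re.Pattern:
    parts = []
    for letter in word.upper():
        if letter not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {letter!r} in {word!r}")
        cls = IUPAC[letter]
        parts.append(cls if len(cls) == 1 else f"[{cls}]")
    return re.compile("".join(parts))


def count_motif_occurrences(seq: str, word: str) -> tuple[int, list[int]]:
    """Number and offsets of (possibly overlapping) sense-strand matches."""
    pattern = iupac_regex(word)
    seq = seq.upper()
    positions = []
    i = 0
    while True:
        m = pattern.search(seq, i)
        if m is None:
            break
        positions.append(m.start())
        i = m.start() + 1
    return len(positions), positions


def _has_match(seq: str, pattern: re.Pattern) -> bool:
    return pattern.search(seq) is not None


@dataclass
class MotifModel:
    """A degenerate IUPAC word with its enrichment statistics."""

    iupac_word: str
    pos_count: int
    neg_count: int
    pos_total: int
    neg_total: int
    p_value: float
    e_value: float
    core_word: str = ""
    core_p_value: float = 1.0

    def matches(self, seq: str) -> bool:
        return _has_match(seq.upper(), iupac_regex(self.iupac_word))


def fisher_presence_p(pos_count, pos_total, neg_count, neg_total) -> float:
    """One-sided (enrichment) Fisher exact p on sequence-level presence."""
    table = [[pos_count, pos_total - pos_count],
             [neg_count, neg_total - neg_count]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def _presence_counts(seqs: list[str], width: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for s in seqs:
        seen = {s[i:i + width] for i in range(len(s) - width + 1)}
        for w in seen:
            counts[w] = counts.get(w, 0) + 1
    return counts


def _count_presence(seqs: list[str], pattern: re.Pattern) -> int:
    return sum(1 for s in seqs if pattern.search(s) is not None)


def _generalize(word: str, pos_seqs, neg_seqs, p0: float,
                max_generalizations: int) -> tuple[str, float]:
    """Greedy IUPAC generalization of a core word.

    One position changes per step; a step is kept only if it strictly lowers
    the Fisher p.  Ties among candidate steps break by lowest p, then
    shortest IUPAC class, then lexicographic code.
    """
    current, current_p = word, p0
    for _ in range(max_generalizations):
        best = None
        for i, letter in enumerate(current):
            base = frozenset(IUPAC[letter])
            for code, cls in IUPAC.items():
                cset = frozenset(cls)
                if not (cset > base):
                    continue
                cand = current[:i] + code + current[i + 1:]
                pat = iupac_regex(cand)
                pc = _count_presence(pos_seqs, pat)
                nc = _count_presence(neg_seqs, pat)
                p = fisher_presence_p(pc, len(pos_seqs), nc, len(neg_seqs))
                key = (p, len(cls), code, i)
                if best is None or key < best[0]:
                    best = (key, cand)
        if best is None or best[0][0] >= current_p:
            break
        current_p = best[0][0]
        current = best[1]
    return current, current_p


def _erase_matches(seqs: list[str], pattern: re.Pattern) -> list[str]:
    """Replace every matched site with N so later rounds cannot reuse it."""
    out = []
    for s in seqs:
        while True:
            m = pattern.search(s)
            if m is None:
                break
            s = s[:m.start()] + "N" * (m.end() - m.start()) + s[m.end():]
        out.append(s)
    return out


def discover_motifs(
    pos_seqs, neg_seqs,
    core_widths=range(4, 9),
    max_generalizations: int = 3,
    e_threshold: float = 0.05,
    max_motifs: int = 3,
) -> list[MotifModel]:
    """DREME-style discriminative motif discovery.

    Returns motifs with e_value <= e_threshold, best first.  The e-value is
    the Fisher p times the number of distinct exact candidate words tested
    (a Bonferroni-style correction).
    """
    if not pos_seqs or not neg_seqs:
        raise ValueError("both sequence sets must be non-empty")
    pos = [s.upper() for s in pos_seqs]
    neg = [s.upper() for s in neg_seqs]
    motifs: list[MotifModel] = []
    for _ in range(max_motifs):
        candidates: list[tuple[str, int, int]] = []
        n_tested = 0
        for width in core_widths:
            pos_counts = _presence_counts(pos, width)
            pos_counts = {w: c for w, c in pos_counts.items()
                          if "N" not in w}
            if not pos_counts:
                continue
            neg_counts = _presence_counts(neg, width)
            n_tested += len(pos_counts)
            for w, pc in pos_counts.items():
                candidates.append((w, pc, neg_counts.get(w, 0)))
        if not candidates:
            break
        words = np.array([c[0] for c in candidates])
        pc = np.array([c[1] for c in candidates])
        nc = np.array([c[2] for c in candidates])
        # one-sided Fisher == hypergeometric upper tail; vectorized ranking
        N = len(pos) + len(neg)
        pvals = stats.hypergeom.sf(pc - 1, N, pc + nc, len(pos))
        order = np.lexsort((words, [len(w) for w in words], pvals))
        best_i = order[0]
        core = str(words[best_i])
        core_p = fisher_presence_p(int(pc[best_i]), len(pos),
                                   int(nc[best_i]), len(neg))
        word, p = _generalize(core, pos, neg, core_p, max_generalizations)
        e_value = p * n_tested
        if e_value > e_threshold:
            break
        pat = iupac_regex(word)
        motifs.append(MotifModel(
            iupac_word=word,
            pos_count=_count_presence(pos, pat),
            neg_count=_count_presence(neg, pat),
            pos_total=len(pos),
            neg_total=len(neg),
            p_value=p,
            e_value=e_value,
            core_word=core,
            core_p_value=core_p,
        ))
        pos = _erase_matches(pos, pat)
    return motifs


def motif_presence_stats(groups: dict[str, list[str]], word: str):
    """Per-group presence proportions and per-sequence counts (Fig.-5B/C style).

    Returns (table, chi2_p, pairwise) where table has one row per non-empty
    group, chi2_p is the chi-square p over the groups x {has, has-not}
    contingency table (no continuity correction), and pairwise holds Welch
    t-test p-values on per-sequence match counts for each group pair.
    """
    import itertools
    import pandas as pd

    pattern = iupac_regex(word)
    rows, counts_by_group = [], {}
    for name, seqs in groups.items():
        if not seqs:
            continue
        counts = [count_motif_occurrences(s, word)[0] for s in seqs]
        has = sum(1 for c in counts if c > 0)
        counts_by_group[name] = np.array(counts, dtype=float)
        rows.append({
            "group": name, "n": len(seqs),
            "n_with_motif": has,
            "proportion_with_motif": has / len(seqs),
            "mean_motifs_per_seq": float(np.mean(counts)),
        })
    table = pd.DataFrame(rows)
    contingency = np.array([
        [r["n_with_motif"], r["n"] - r["n_with_motif"]] for r in rows
    ])
    if contingency.shape[0] >= 2 and contingency.sum(axis=0).min() > 0:
        chi2_p = float(stats.chi2_contingency(contingency, correction=False)[1])
    else:
        chi2_p = float("nan")
    pairwise = []
    for ga, gb in itertools.combinations(counts_by_group, 2):
        res = stats.ttest_ind(counts_by_group[ga], counts_by_group[gb],
                              equal_var=False)
        pairwise.append({"groupA": ga, "groupB": gb,
                         "t_stat": float(res.statistic),
                         "p_value": float(res.pvalue)})
    return table, chi2_p, pd.DataFrame(pairwise)


@dataclass
class PositionalProfile:
    """Smoothed motif-occurrence density on the meta-exon axis."""

    flank_len: int
    exon_bins: int
    raw: np.ndarray        # unsmoothed per-position match count / n sequences
    density: np.ndarray    # Gaussian-smoothed raw
    n_sequences: int
    n_matches: int         # matches mapped onto the axis

    @property
    def axis_length(self) -> int:
        return 2 * self.flank_len + self.exon_bins

    def region_of(self, index: int) -> str:
        if index < self.flank_len:
            return "upstream_intron"
        if index < self.flank_len + self.exon_bins:
            return "exon"
        return "downstream_intron"

    def region_slices(self) -> dict[str, slice]:
        f, e = self.flank_len, self.exon_bins
        return {
            "upstream_intron": slice(0, f),
            "exon": slice(f, f + e),
            "downstream_intron": slice(f + e, 2 * f + e),
        }


def positional_profile(
    events_with_sequences, word: str,
    flank_len: int = 250, exon_bins: int = 100, sigma: float = 10.0,
) -> PositionalProfile:
    """Meta-exon density of motif-match centers for one sequence group.

    ``events_with_sequences`` is an iterable of EventSequences (or any object
    with upstream_flank/exon_seq/downstream_flank).  Intronic positions are
    absolute distances from the adjacent splice site; exonic positions are
    scaled to ``exon_bins`` bins.
    """
    axis = np.zeros(2 * flank_len + exon_bins)
    n_seq = 0
    n_matches = 0
    for ev in events_with_sequences:
        n_seq += 1
        half = len(word) / 2.0
        up, exon, down = ev.upstream_flank, ev.exon_seq, ev.downstream_flank
        for region, seq in (("up", up), ("exon", exon), ("down", down)):
            if not seq:
                continue
            _count, offsets = count_motif_occurrences(seq, word)
            for off in offsets:
                center = off + half
                if region == "up":
                    # distance from 3'ss: last nt of flank is distance 1
                    dist = len(up) - center
                    if dist > flank_len:
                        continue
                    idx = flank_len - dist
                elif region == "exon":
                    frac = center / len(exon)
                    idx = flank_len + min(int(frac * exon_bins), exon_bins - 1)
                else:
                    if center > flank_len:
                        continue
                    idx = flank_len + exon_bins + min(int(center), flank_len - 1)
                axis[int(idx)] += 1
                n_matches += 1
    raw = axis / n_seq if n_seq else axis
    density = gaussian_filter1d(raw, sigma=sigma, mode="constant") if sigma > 0 else raw.copy()
    return PositionalProfile(flank_len, exon_bins, raw, density, n_seq, n_matches)
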