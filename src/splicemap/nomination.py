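"""Matching discovered motifs to an RBP compendium and nominating regulators.

The compendium is read from MEME-minimal motif files (RNA alphabet accepted,
U mapped to T).  Matching is a transparent Tomtom-style comparison: for each
target the query position-probability matrix is slid over it, alignments
with at least four overlapping columns are scored by the mean per-column
Pearson correlation of probability columns, and significance comes from a
seeded column-shuffle permutation null.

Regulator nomination then asks whether, across a patient cohort, the
inclusion of each regulated exon co-varies with the candidate RBP's
expression in the direction the knockdown data predict: an exon whose
inclusion drops when the upstream kinase is depleted should correlate
positively with the regulator's expression (and vice versa), assuming the
kinase acts positively on the regulator.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import IUPAC, PositionalProfile

logger = logging.getLogger(__name__)

NUCS = "ACGT"


@dataclass
class CompendiumMotif:
    rbp_name: str
    ppm: np.ndarray  # (width, 4), rows sum to 1
    source_id: str = ""

    def __post_init__(self):
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.ppm.ndim != 2 or self.ppm.shape[1] != 4:
            raise ValueError("ppm must be (width, 4)")
        if (self.ppm < 0).any() or not np.allclose(self.ppm.sum(axis=1), 1, atol=1e-9):
            raise ValueError(f"ppm rows of {self.rbp_name} must be probabilities summing to 1")


def iupac_to_ppm(word: str) -> np.ndarray:
    """Uniform probability over each position's IUPAC class, 0 elsewhere."""
    rows = []
    for letter in word.upper():
        if letter not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {letter!r}")
        cls = IUPAC[letter]
        row = np.array([1.0 / len(cls) if n in cls else 0.0 for n in NUCS])
        rows.append(row)
    return np.array(rows)


def read_meme_compendium(path) -> list[CompendiumMotif]:
    """Read motifs from a MEME-minimal file via Bio.motifs; U is mapped to T."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = []
    for m in parsed:
        letters = sorted(m.alphabet, key=lambda c: NUCS.index("T" if c == "U" else c))
        width = m.counts.length
        mat = np.zeros((width, 4))
        for letter in letters:
            col = NUCS.index("T" if letter == "U" else letter)
            mat[:, col] = m.counts[letter]
        row_sums = mat.sum(axis=1, keepdims=True)
        mat = mat / row_sums
        name = m.name or getattr(m, "base_id", "") or "motif"
        out.append(CompendiumMotif(rbp_name=name, ppm=mat, source_id=name))
    return out


@dataclass
class MotifMatch:
    rbp_name: str
    offset: int
    similarity: float
    p_value: float


def _column_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r between two 4-vectors; constant columns: 1 if equal else 0."""
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.dot(a - a.mean(), b - b.mean()) / (4 * sa * sb))


def _best_alignment(query: np.ndarray, target: np.ndarray,
                    min_overlap: int = 4) -> tuple[int, float]:
    """Best (offset, mean column Pearson) of query slid along target.

    Offset is the index of the target column aligned with query column 0
    (negative when the query overhangs the target's left edge).
    """
    qw, tw = len(query), len(target)
    best_off, best_sim = 0, -np.inf
    for off in range(-(qw - min_overlap), tw - min_overlap + 1):
        lo = max(0, off)
        hi = min(tw, off + qw)
        if hi - lo < min_overlap:
            continue
        sims = [
            _column_correlation(query[j - off], target[j]) for j in range(lo, hi)
        ]
        sim = float(np.mean(sims))
        if sim > best_sim:
            best_off, best_sim = off, sim
    return best_off, best_sim


def match_motif_to_compendium(
    query_ppm: np.ndarray,
    compendium: list[CompendiumMotif],
    n_permutations: int = 200,
    seed: int = 0,
    min_overlap: int = 4,
) -> list[MotifMatch]:
    """Rank compendium motifs by similarity to the query PPM.

    The permutation null shuffles each target's columns ``n_permutations``
    times (seeded) and recomputes the best alignment similarity; the p-value
    uses the add-one estimator, counting only strictly better permutations
    as more extreme.  (Shuffles of a target identical to the query can
    recreate the perfect score; counting those ties against the match would
    penalize exact matches, which must rank first.)  Results are sorted by
    p then similarity.
    """
    query_ppm = np.asarray(query_ppm, dtype=float)
    if len(query_ppm) < min_overlap:
        raise ValueError(f"query width must be >= {min_overlap}")
    if not compendium:
        raise ValueError("compendium is empty")
    rng = np.random.default_rng(seed)
    matches = []
    for target in compendium:
        off, sim = _best_alignment(query_ppm, target.ppm, min_overlap)
        exceed = 0
        tw = len(target.ppm)
        for _ in range(n_permutations):
            perm = target.ppm[rng.permutation(tw)]
            _, psim = _best_alignment(query_ppm, perm, min_overlap)
            if psim > sim + 1e-12:
                exceed += 1
        p = (1 + exceed) / (1 + n_permutations)
        matches.append(MotifMatch(target.rbp_name, off, sim, p))
    return sorted(matches, key=lambda m: (m.p_value, -m.similarity))


@dataclass
class ConcordanceRecord:
    event_id: str
    rbp_name: str
    rho: float
    p_value: float
    n: int
    regulation: str            # direction under regulator-kinase depletion
    usable: bool = True
    expected_sign: str = ""    # "+" or "-"
    concordant: bool | None = None


def spearman_with_p(x: np.ndarray, y: np.ndarray,
                    exact_below: int = 9) -> tuple[float, float]:
    """Spearman rho with average-rank ties.

    The two-sided p comes from exact permutation enumeration for
    n < ``exact_below`` and the large-sample t approximation otherwise.
    """
    n = len(x)
    rho = float(stats.spearmanr(x, y).statistic)
    if math.isnan(rho):
        return rho, float("nan")
    if n < exact_below:
        a = stats.rankdata(x)
        b = stats.rankdata(y)
        a = tuple(a - a.mean())
        b = tuple(b - b.mean())
        # |rho| order matches |a.perm| because the rank scales are fixed
        obs = abs(sum(u * v for u, v in zip(a, b))) - 1e-12
        count = total = 0
        for perm in itertools.permutations(b):
            count += abs(sum(u * v for u, v in zip(a, perm))) >= obs
            total += 1
        return rho, count / total
    return rho, float(stats.spearmanr(x, y).pvalue)


def correlate_psi_expression(
    psi: pd.DataFrame, expression: pd.DataFrame,
    rbp_list, events,
    min_pairs: int = 10,
) -> list[ConcordanceRecord]:
    """Spearman correlation of each event's PSI with each RBP's expression.

    ``psi`` is events x samples, ``expression`` genes x samples; only shared
    samples are used, pairwise complete per (event, RBP).  Records with
    fewer than ``min_pairs`` complete pairs or zero PSI variance are flagged
    unusable.
    """
    shared = psi.columns.intersection(expression.columns)
    if len(shared) < min_pairs:
        raise ValueError(f"only {len(shared)} shared samples (need >= {min_pairs})")
    records = []
    for ev in events:
        if hasattr(ev, "event_id"):
            event_id, regulation = ev.event_id, ev.regulation
        elif isinstance(ev, (tuple, list)):
            event_id, regulation = ev
        else:
            event_id, regulation = ev, ""
        if event_id not in psi.index:
            logger.warning("event %s absent from PSI matrix; skipped", event_id)
            continue
        pvals = psi.loc[event_id, shared].to_numpy(dtype=float)
        for rbp in rbp_list:
            if rbp not in expression.index:
                logger.warning("RBP %s absent from expression matrix; skipped", rbp)
                continue
            evals = expression.loc[rbp, shared].to_numpy(dtype=float)
            mask = ~(np.isnan(pvals) | np.isnan(evals))
            x, y = pvals[mask], evals[mask]
            if mask.sum() < min_pairs or np.ptp(x) == 0 or np.ptp(y) == 0:
                records.append(ConcordanceRecord(
                    event_id, rbp, float("nan"), float("nan"),
                    int(mask.sum()), regulation, usable=False))
                continue
            rho, p = spearman_with_p(x, y)
            records.append(ConcordanceRecord(
                event_id, rbp, rho, p, int(mask.sum()), regulation))
    return records


def classify_concordance(
    records, alpha: float = 0.05, regulator_effect: str = "positive",
):
    """Set expected_sign/concordant flags and summarize per RBP.

    With a positive kinase->regulator effect, exons down-regulated on kinase
    depletion should correlate positively with the regulator's expression
    (expected sign "+") and up-regulated exons negatively.  A negative
    effect flips the rule.  Concordant = correct sign and p <= alpha.
    Re-running on already-classified records leaves them unchanged.
    """
    if regulator_effect not in ("positive", "negative"):
        raise ValueError("regulator_effect must be 'positive' or 'negative'")
    flip = regulator_effect == "negative"
    for rec in records:
        if rec.regulation not in ("up", "down"):
            rec.expected_sign = ""
            rec.concordant = None
            continue
        positive = rec.regulation == "down"
        if flip:
            positive = not positive
        rec.expected_sign = "+" if positive else "-"
        if not rec.usable or math.isnan(rec.rho):
            rec.concordant = None
            continue
        sign_ok = (rec.rho > 0) == positive and rec.rho != 0
        rec.concordant = bool(sign_ok and rec.p_value <= alpha)
    summary = []
    by_rbp: dict[str, list[ConcordanceRecord]] = {}
    for rec in records:
        by_rbp.setdefault(rec.rbp_name, []).append(rec)
    for rbp, recs in sorted(by_rbp.items()):
        sig = [r for r in recs if r.usable and not math.isnan(r.p_value)
               and r.p_value <= alpha and r.regulation in ("up", "down")]
        conc = [r for r in sig if r.concordant]
        summary.append({
            "rbp_name": rbp,
            "n_records": len(recs),
            "n_significant": len(sig),
            "n_concordant": len(conc),
            "fraction_concordant": len(conc) / len(sig) if sig else float("nan"),
        })
    return records, pd.DataFrame(summary)


# Region(s) where binding predicts the observed depletion response, for a
# regulator that activates inclusion from the downstream intron and
# represses from the upstream intron or exon (the RBFOX-family RNA map).
DEFAULT_POSITION_RULE = {
    "down": ("downstream_intron",),
    "up": ("upstream_intron", "exon"),
}


def positional_consistency(
    profiles: dict[str, PositionalProfile],
    rule: dict[str, tuple[str, ...]] | None = None,
) -> dict:
    """Check whether each direction's profile peaks where the rule predicts.

    Returns, per direction, the peak region/position, a peak/background
    ratio (peak density over mean density) and a verdict: ``consistent``,
    ``inconsistent`` or ``no_signal``.
    """
    rule = rule or DEFAULT_POSITION_RULE
    report: dict[str, dict] = {}
    for direction, profile in profiles.items():
        if profile.density.max() <= 0:
            report[direction] = {"verdict": "no_signal"}
            continue
        idx = int(np.argmax(profile.density))
        region = profile.region_of(idx)
        mean = float(profile.density.mean())
        entry = {
            "peak_index": idx,
            "peak_region": region,
            "peak_density": float(profile.density[idx]),
            "peak_background_ratio": float(profile.density[idx] / mean) if mean > 0 else float("inf"),
        }
        expected = rule.get(direction)
        if expected is None:
            entry["verdict"] = "no_rule"
        else:
            entry["expected_regions"] = list(expected)
            entry["verdict"] = "consistent" if region in expected else "inconsistent"
        report[direction] = entry
    return report


def correlate_gene_pair(expression: pd.DataFrame, gene_a: str, gene_b: str):
    """Pearson correlation of two genes' expression over pairwise-complete samples."""
    for g in (gene_a, gene_b):
        if g not in expression.index:
            raise KeyError(f"gene {g!r} absent from expression matrix")
    a = expression.loc[gene_a].to_numpy(dtype=float)
    b = expression.loc[gene_b].to_numpy(dtype=float)
    mask = ~(np.isnan(a) | np.isnan(b))
    if mask.sum() < 3:
        raise ValueError("need >= 3 shared samples")
    a, b = a[mask], b[mask]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)
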