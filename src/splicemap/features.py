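"""Sequence features of cassette exons.

Splice-site strength is scored with first-order position weight matrices in
log-odds (bits) over the de facto standard windows: the donor 9-mer covers
the last 3 exonic + first 6 intronic nucleotides of the exon/downstream
intron junction, the acceptor 23-mer the last 20 intronic + first 3 exonic
nucleotides of the upstream-intron/exon junction.  The branchpoint and
polypyrimidine tract (PPT) are located with a transparent heuristic: the
branchpoint is the adenine in a 15-250 nt window upstream of the acceptor
best matching the yUnAy consensus, and the PPT is the maximum-weight
contiguous segment between branchpoint and acceptor-3 under weights
T=+2, C=+1, A=G=-2.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exons import CassetteExonEvent, reverse_complement

logger = logging.getLogger(__name__)

NUCS = "ACGT"
DONOR_EXONIC = 3     # exonic nt in the donor window
DONOR_INTRONIC = 6   # intronic nt in the donor window
ACCEPTOR_INTRONIC = 20
ACCEPTOR_EXONIC = 3
DONOR_WIDTH = DONOR_EXONIC + DONOR_INTRONIC
ACCEPTOR_WIDTH = ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC

PPT_WEIGHTS = {"T": 2.0, "C": 1.0, "A": -2.0, "G": -2.0, "N": -2.0}


class TrainingError(ValueError):
    """Raised when too few usable sites are available to fit the model."""


@dataclass
class SpliceSiteModel:
    """Positional log-odds matrices (bits) for donor and acceptor sites."""

    donor_matrix: np.ndarray     # (DONOR_WIDTH, 4)
    acceptor_matrix: np.ndarray  # (ACCEPTOR_WIDTH, 4)
    background: np.ndarray       # (4,), sums to 1
    pseudocount: float

    def score_window(self, window: str, which: str) -> float | None:
        matrix = self.donor_matrix if which == "donor" else self.acceptor_matrix
        if len(window) != matrix.shape[0]:
            return None
        total = 0.0
        for pos, letter in enumerate(window):
            j = NUCS.find(letter)
            if j < 0:
                return None  # N or other ambiguity: score undefined
            total += matrix[pos, j]
        return total


def donor_window_coords(event: CassetteExonEvent) -> tuple[int, int]:
    """Genomic interval of the donor 9-mer (transcript orientation handled)."""
    s, e = event.exon
    if event.strand == "+":
        return e - DONOR_EXONIC, e + DONOR_INTRONIC
    return s - DONOR_INTRONIC, s + DONOR_EXONIC


def acceptor_window_coords(event: CassetteExonEvent) -> tuple[int, int]:
    s, e = event.exon
    if event.strand == "+":
        return s - ACCEPTOR_INTRONIC, s + ACCEPTOR_EXONIC
    return e - ACCEPTOR_EXONIC, e + ACCEPTOR_INTRONIC


def _fetch_window(genome, event, coords) -> str | None:
    a, b = coords
    contig = genome[event.chrom]
    if a < 0 or b > len(contig):
        return None
    seq = str(contig[a:b]).upper()
    if event.strand == "-":
        seq = reverse_complement(seq)
    return seq


def extract_site_windows(genome, event: CassetteExonEvent) -> tuple[str | None, str | None]:
    """(donor, acceptor) windows in transcript orientation, or None if clipped.

    Windows requiring more intronic sequence than the flanking intron holds
    are returned as None (score absent).
    """
    up_len = event.upstream_intron[1] - event.upstream_intron[0]
    down_len = event.downstream_intron[1] - event.downstream_intron[0]
    donor = (
        _fetch_window(genome, event, donor_window_coords(event))
        if down_len >= DONOR_INTRONIC else None
    )
    acceptor = (
        _fetch_window(genome, event, acceptor_window_coords(event))
        if up_len >= ACCEPTOR_INTRONIC else None
    )
    return donor, acceptor


def _counts_to_logodds(windows: list[str], width: int, pseudocount: float,
                       background: np.ndarray) -> np.ndarray:
    counts = np.zeros((width, 4))
    for w in windows:
        for pos, letter in enumerate(w):
            counts[pos, NUCS.index(letter)] += 1
    n = len(windows)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    return np.log2(probs / background[None, :])


def train_splice_site_model(
    constitutive_events, genome, pseudocount: float = 0.5, min_sites: int = 20
) -> SpliceSiteModel:
    """Fit donor/acceptor PWMs from constitutive-exon junctions.

    Windows containing N are skipped (logged).  The background is the overall
    nucleotide composition of all retained windows.
    """
    donors, acceptors = [], []
    for ev in constitutive_events:
        d, a = extract_site_windows(genome, ev)
        for window, bucket, label in ((d, donors, "donor"), (a, acceptors, "acceptor")):
            if window is None:
                continue
            if any(c not in NUCS for c in window):
                logger.warning("%s window of %s contains N; skipped", label, ev.event_id)
                continue
            bucket.append(window)
    if len(donors) < min_sites or len(acceptors) < min_sites:
        raise TrainingError(
            f"need >= {min_sites} usable sites (got {len(donors)} donor, "
            f"{len(acceptors)} acceptor)"
        )
    pooled = "".join(donors) + "".join(acceptors)
    bg_counts = np.array([pooled.count(n) for n in NUCS], dtype=float)
    background = bg_counts / bg_counts.sum()
    return SpliceSiteModel(
        donor_matrix=_counts_to_logodds(donors, DONOR_WIDTH, pseudocount, background),
        acceptor_matrix=_counts_to_logodds(acceptors, ACCEPTOR_WIDTH, pseudocount, background),
        background=background,
        pseudocount=pseudocount,
    )


def score_splice_sites(event, genome, model: SpliceSiteModel):
    """(donor_score, acceptor_score) in bits; None where the window is unusable."""
    donor, acceptor = extract_site_windows(genome, event)
    d = model.score_window(donor, "donor") if donor else None
    a = model.score_window(acceptor, "acceptor") if acceptor else None
    return d, a


def gc_content(seq: str) -> float | None:
    """(G+C)/(A+C+G+T); N excluded from both counts.  None if nothing remains."""
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        return None
    return gc / (gc + at)


def _bp_consensus_score(seq: str, a_idx: int) -> float:
    """Match of the 5-mer around an adenine to yUnAy (y=C/T, U=T).

    One point per matching constraint position (offsets -3, -2, +1 from the
    A); out-of-range positions score 0.
    """
    score = 0.0
    for off, allowed in ((-3, "CT"), (-2, "T"), (1, "CT")):
        j = a_idx + off
        if 0 <= j < len(seq) and seq[j] in allowed:
            score += 1.0
    return score


def _best_segment(weights: list[float]) -> tuple[int, int, float]:
    """Max-sum contiguous segment (empty allowed, sum 0).

    Ties broken toward the acceptor (larger end index), then shorter.
    Returns (start, end, score) with [start, end) indices into weights.
    """
    best = (0, 0, 0.0)
    prefix = 0.0
    min_prefix = 0.0
    min_idx = 0
    for j, w in enumerate(weights):
        prefix += w
        score = prefix - min_prefix
        if score > best[2] or (score == best[2] and score > 0 and j + 1 > best[1]):
            best = (min_idx, j + 1, score)
        if prefix <= min_prefix:  # prefer later start (shorter segment) on ties
            min_prefix = prefix
            min_idx = j + 1
    return best


def branchpoint_and_ppt(
    upstream_intron_3prime_seq: str,
    search_window: tuple[int, int] = (15, 250),
):
    """Locate the branchpoint adenine and polypyrimidine tract.

    The input is the 3' end of the upstream intron in transcript orientation,
    ending at the acceptor (last character is the final intron nucleotide).
    Distances count nucleotides from the acceptor: the last character is at
    distance 1.

    Returns (bp_distance, bp_score, ppt_length, ppt_score); bp_distance and
    bp_score are None when no adenine lies in the search window.
    """
    seq = upstream_intron_3prime_seq.upper()
    L = len(seq)
    lo, hi = search_window
    best_a = None
    best_score = -1.0
    # scan from acceptor outward so that ties resolve to the closest adenine
    for dist in range(lo, min(hi, L) + 1):
        i = L - dist
        if seq[i] != "A":
            continue
        sc = _bp_consensus_score(seq, i)
        if sc > best_score:
            best_score = sc
            best_a = i
    if best_a is None:
        bp_distance = bp_score = None
        region_start = max(0, L - hi)
    else:
        bp_distance = L - best_a
        bp_score = best_score
        region_start = best_a + 1
    region_end = max(region_start, L - 3)  # PPT ends 3 nt before the acceptor
    region = seq[region_start:region_end]
    weights = [PPT_WEIGHTS.get(c, -2.0) for c in region]
    start, end, score = _best_segment(weights)
    return bp_distance, bp_score, end - start, score


@dataclass
class ExonFeatureRecord:
    event_id: str
    group: str
    donor_score: float | None = None
    acceptor_score: float | None = None
    ppt_length: float | None = None
    ppt_score: float | None = None
    bp_distance: float | None = None
    gc_exon: float | None = None
    gc_upstream_intron: float | None = None
    gc_downstream_intron: float | None = None


FEATURE_COLUMNS = [
    "donor_score", "acceptor_score", "ppt_length", "ppt_score", "bp_distance",
    "gc_exon", "gc_upstream_intron", "gc_downstream_intron",
]


def compute_event_features(
    event: CassetteExonEvent, genome, model: SpliceSiteModel,
    group: str | None = None, bp_window: tuple[int, int] = (15, 250),
    gc_flank_window: int | None = None,
) -> ExonFeatureRecord:
    """All per-event features.  Intronic GC spans the full flanking intron
    unless ``gc_flank_window`` restricts it to a window adjacent to the exon."""
    donor, acceptor = score_splice_sites(event, genome, model)
    contig = genome[event.chrom]

    def fetch(a, b):
        return str(contig[max(a, 0):min(b, len(contig))]).upper()

    li = event.genomic_left_intron
    ri = event.genomic_right_intron
    if gc_flank_window:
        # restrict each intron to the window adjacent to the exon
        li = (max(li[0], li[1] - gc_flank_window), li[1])
        ri = (ri[0], min(ri[1], ri[0] + gc_flank_window))
    left_seq = fetch(*li)
    right_seq = fetch(*ri)
    exon_seq = fetch(*event.exon)
    if event.strand == "+":
        up_seq, down_seq = left_seq, right_seq
    else:
        up_seq = reverse_complement(right_seq)
        down_seq = reverse_complement(left_seq)
        exon_seq = reverse_complement(exon_seq)
    tail = up_seq[-bp_window[1]:]
    bp_distance, _bp_score, ppt_length, ppt_score = branchpoint_and_ppt(tail, bp_window)
    return ExonFeatureRecord(
        event_id=event.event_id,
        group=group or event.regulation,
        donor_score=donor,
        acceptor_score=acceptor,
        ppt_length=float(ppt_length),
        ppt_score=float(ppt_score),
        bp_distance=None if bp_distance is None else float(bp_distance),
        gc_exon=gc_content(exon_seq),
        gc_upstream_intron=gc_content(up_seq),
        gc_downstream_intron=gc_content(down_seq),
    )


def features_to_frame(records) -> pd.DataFrame:
    rows = [
        {"event_id": r.event_id, "group": r.group,
         **{c: getattr(r, c) for c in FEATURE_COLUMNS}}
        for r in records
    ]
    return pd.DataFrame(rows)


def compare_feature_groups(records, group_labels=None) -> pd.DataFrame:
    """Pairwise Welch t-tests per feature across groups.

    Absent values are dropped per feature; a (feature, pair) with an empty
    group is skipped and logged.
    """
    df = records if isinstance(records, pd.DataFrame) else features_to_frame(records)
    groups = group_labels or sorted(df["group"].unique())
    rows = []
    for feature in FEATURE_COLUMNS:
        for ga, gb in itertools.combinations(groups, 2):
            xa = df.loc[df["group"] == ga, feature].dropna().to_numpy(dtype=float)
            xb = df.loc[df["group"] == gb, feature].dropna().to_numpy(dtype=float)
            if len(xa) < 2 or len(xb) < 2:
                logger.warning("skipping %s: %s vs %s (too few finite values)",
                               feature, ga, gb)
                continue
            stat = stats.ttest_ind(xa, xb, equal_var=False)
            rows.append({
                "feature": feature, "groupA": ga, "groupB": gb,
                "meanA": float(xa.mean()), "meanB": float(xb.mean()),
                "t_stat": float(stat.statistic), "p_value": float(stat.pvalue),
                "nA": len(xa), "nB": len(xb),
            })
    return pd.DataFrame(rows)
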