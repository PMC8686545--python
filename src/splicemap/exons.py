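"""Gene models, cassette-exon events and strand-aware sequence extraction.

Coordinates are 0-based half-open internally.  GTF input is converted from
its native 1-based closed convention at the boundary; BED-like exports stay
0-based half-open.  "Upstream" and "downstream" always refer to transcript
orientation: on the minus strand the upstream intron is genomically to the
right of the exon.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import gffutils
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

REGULATION_LABELS = ("up", "down", "reference_cassette", "reference_constitutive")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GtfParseError(ValueError):
    """Raised when a GTF record cannot be interpreted."""


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered set of transcripts, each a sorted exon chain."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: Mapping[str, tuple[tuple[int, int], ...]]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")
        for tx_id, exons in self.transcripts.items():
            if not exons:
                raise ValueError(f"transcript {tx_id} of {self.gene_id} has no exons")
            for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
                if s1 < e0:
                    raise ValueError(
                        f"overlapping/unsorted exons in transcript {tx_id} of {self.gene_id}"
                    )


@dataclass
class CassetteExonEvent:
    """One alternative exon with its flanking introns (genomic coordinates).

    ``upstream_intron`` is 5' of the exon in transcript orientation; on the
    minus strand it is genomically downstream of the exon.  ``delta_psi`` is
    present only for regulated (up/down) events.
    """

    event_id: str
    gene_id: str
    chrom: str
    strand: str
    exon: tuple[int, int]
    upstream_intron: tuple[int, int]
    downstream_intron: tuple[int, int]
    regulation: str
    delta_psi: float | None = None

    def __post_init__(self):
        if self.regulation not in REGULATION_LABELS:
            raise ValueError(f"unknown regulation label {self.regulation!r}")
        has_dpsi = self.delta_psi is not None
        if has_dpsi != (self.regulation in ("up", "down")):
            raise ValueError(
                "delta_psi must be present exactly for regulated (up/down) events"
            )
        s, e = self.exon
        for name, (a, b) in (
            ("upstream_intron", self.upstream_intron),
            ("downstream_intron", self.downstream_intron),
        ):
            if not (b == s or a == e):
                raise ValueError(
                    f"{name} {a}-{b} not adjacent to exon {s}-{e} in {self.event_id}"
                )

    @property
    def genomic_left_intron(self) -> tuple[int, int]:
        """The intron genomically left of the exon, regardless of strand."""
        return self.upstream_intron if self.strand == "+" else self.downstream_intron

    @property
    def genomic_right_intron(self) -> tuple[int, int]:
        return self.downstream_intron if self.strand == "+" else self.upstream_intron


@dataclass
class EventSequences:
    """Sense-strand (transcript orientation) sequences of an event."""

    upstream_flank: str
    exon_seq: str
    downstream_flank: str
    flank_len: int
    truncated: bool

    def concatenated(self) -> str:
        return self.upstream_flank + self.exon_seq + self.downstream_flank


def load_gene_models(gtf_path) -> list[GeneModel]:
    """Read a GTF and group exon features into :class:`GeneModel` objects.

    Coordinates are converted from 1-based closed to 0-based half-open.
    Exons lacking a transcript_id attribute are rejected (logged); a gene
    whose transcripts disagree on strand is an error.
    """
    try:
        from gffutils.exceptions import EmptyInputError
    except ImportError:  # older gffutils layouts
        EmptyInputError = ()
    try:
        db = gffutils.create_db(
            str(gtf_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except EmptyInputError:
        return []
    except Exception as exc:  # gffutils wraps line-level failures
        raise GtfParseError(f"failed to parse GTF {gtf_path}: {exc}") from exc

    genes: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        gene_ids = feat.attributes.get("gene_id")
        tx_ids = feat.attributes.get("transcript_id")
        if not gene_ids:
            raise GtfParseError(f"exon at {feat.seqid}:{feat.start} lacks gene_id")
        if not tx_ids:
            logger.warning(
                "exon at %s:%d-%d has no transcript_id; record skipped",
                feat.seqid, feat.start, feat.end,
            )
            continue
        gid, tid = gene_ids[0], tx_ids[0]
        rec = genes.setdefault(gid, {"chrom": feat.seqid, "strand": feat.strand, "tx": {}})
        if rec["strand"] != feat.strand:
            raise GtfParseError(f"gene {gid} has transcripts on both strands")
        if rec["chrom"] != feat.seqid:
            raise GtfParseError(f"gene {gid} spans multiple contigs")
        # GTF is 1-based closed; internal representation 0-based half-open.
        rec["tx"].setdefault(tid, []).append((feat.start - 1, feat.end))

    models = []
    for gid, rec in genes.items():
        transcripts = {
            tid: tuple(sorted(exons)) for tid, exons in sorted(rec["tx"].items())
        }
        models.append(GeneModel(gid, rec["chrom"], rec["strand"], transcripts))
    return sorted(models, key=lambda m: m.gene_id)


def _is_single_cassette(exon, containing, lacking) -> bool:
    """True if some transcript lacking the exon equals a containing one minus it."""
    for tx_in in containing:
        reduced = tuple(e for e in tx_in if e != exon)
        for tx_out in lacking:
            if tuple(tx_out) == reduced:
                return True
    return False


def _flanking_introns(exon, transcripts):
    """Shortest flanking introns over all transcripts containing the exon.

    Returns (left_intron, right_intron) in genomic order, or None if the exon
    is terminal in every containing transcript.
    """
    lefts, rights = [], []
    for exons in transcripts:
        if exon not in exons:
            continue
        i = exons.index(exon)
        if i == 0 or i == len(exons) - 1:
            continue
        lefts.append((exons[i - 1][1], exon[0]))
        rights.append((exon[1], exons[i + 1][0]))
    if not lefts:
        return None
    left = max(lefts, key=lambda iv: iv[0])     # shortest = latest start
    right = min(rights, key=lambda iv: iv[1])   # shortest = earliest end
    return left, right


def build_reference_sets(
    models: Iterable[GeneModel],
    expressed_genes: set[str],
    regulated_events: Iterable[CassetteExonEvent],
) -> tuple[list[CassetteExonEvent], list[CassetteExonEvent]]:
    """Classify internal exons of non-regulated expressed genes.

    Reference cassette exons are internal exons present in >=1 but <100% of
    the gene's transcripts (restricted to single-cassette alternatives);
    reference constitutive exons are internal exons present in every
    transcript.  Genes hosting regulated events contribute nothing.
    """
    regulated_genes = {ev.gene_id for ev in regulated_events}
    cassette, constitutive = [], []
    for model in models:
        if model.gene_id not in expressed_genes or model.gene_id in regulated_genes:
            continue
        tx_list = list(model.transcripts.values())
        n_tx = len(tx_list)
        seen: set[tuple[int, int]] = set()
        for exons in tx_list:
            seen.update(exons)
        for exon in sorted(seen):
            containing = [t for t in tx_list if exon in t]
            internal_somewhere = any(
                0 < t.index(exon) < len(t) - 1 for t in containing
            )
            if not internal_somewhere:
                continue  # first or last wherever it appears
            flanks = _flanking_introns(exon, tx_list)
            if flanks is None:
                continue
            left, right = flanks
            if model.strand == "+":
                up, down = left, right
            else:
                up, down = right, left
            if len(containing) == n_tx:
                label = "reference_constitutive"
            else:
                lacking = [t for t in tx_list if exon not in t]
                if not _is_single_cassette(exon, containing, lacking):
                    continue  # multi-exon alternative
                label = "reference_cassette"
            ev = CassetteExonEvent(
                event_id=f"{model.gene_id}:{model.chrom}:{exon[0]}-{exon[1]}",
                gene_id=model.gene_id,
                chrom=model.chrom,
                strand=model.strand,
                exon=exon,
                upstream_intron=up,
                downstream_intron=down,
                regulation=label,
            )
            (constitutive if label == "reference_constitutive" else cassette).append(ev)
    return cassette, constitutive


def extract_event_sequences(
    genome: Fasta, event: CassetteExonEvent, flank_len: int
) -> EventSequences:
    """Extract exon and flanking-intron sequence in transcript orientation.

    Flanks are clipped to the flanking intron (never extending into the
    neighbouring exon) and to contig bounds; ``truncated`` records clipping.
    """
    if flank_len < 1:
        raise ValueError("flank_len must be >= 1")
    if event.chrom not in genome:
        raise KeyError(f"contig {event.chrom!r} absent from FASTA")
    contig = genome[event.chrom]
    clen = len(contig)
    s, e = event.exon
    if s < 0 or e > clen:
        raise IndexError(f"exon {s}-{e} outside contig {event.chrom} (len {clen})")

    def fetch(a, b):
        return str(contig[a:b]).upper()

    left = event.genomic_left_intron
    right = event.genomic_right_intron
    la = max(left[0], s - flank_len, 0)
    left_seq = fetch(la, s)
    rb = min(right[1], e + flank_len, clen)
    right_seq = fetch(e, rb)
    truncated = len(left_seq) < flank_len or len(right_seq) < flank_len
    exon_seq = fetch(s, e)
    if event.strand == "+":
        up, down = left_seq, right_seq
    else:
        exon_seq = reverse_complement(exon_seq)
        up = reverse_complement(right_seq)
        down = reverse_complement(left_seq)
    return EventSequences(up, exon_seq, down, flank_len, truncated)


EVENT_TABLE_COLUMNS = [
    "event_id", "gene_id", "chrom", "strand", "exon_start", "exon_end",
    "upstream_intron_start", "upstream_intron_end",
    "downstream_intron_start", "downstream_intron_end",
    "regulation", "delta_psi",
]


def write_event_table(events: Sequence[CassetteExonEvent], path) -> None:
    """Write events as TSV (0-based half-open coordinates)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(EVENT_TABLE_COLUMNS)
        for ev in events:
            w.writerow([
                ev.event_id, ev.gene_id, ev.chrom, ev.strand,
                ev.exon[0], ev.exon[1],
                ev.upstream_intron[0], ev.upstream_intron[1],
                ev.downstream_intron[0], ev.downstream_intron[1],
                ev.regulation,
                "" if ev.delta_psi is None else repr(ev.delta_psi),
            ])


def read_event_table(path) -> list[CassetteExonEvent]:
    """Read a TSV event table written by :func:`write_event_table`.

    Regulation labels are normalized to lower case; rows with an unknown
    label are rejected with a message, non-integer coordinates are a parse
    error.
    """
    events = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            regulation = row["regulation"].strip().lower()
            if regulation not in REGULATION_LABELS:
                raise ValueError(
                    f"{path} line {lineno}: unknown regulation label {row['regulation']!r}"
                )
            try:
                coords = {
                    k: int(row[k]) for k in (
                        "exon_start", "exon_end",
                        "upstream_intron_start", "upstream_intron_end",
                        "downstream_intron_start", "downstream_intron_end",
                    )
                }
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: non-integer coordinate") from exc
            dpsi_raw = (row.get("delta_psi") or "").strip()
            events.append(CassetteExonEvent(
                event_id=row["event_id"],
                gene_id=row["gene_id"],
                chrom=row["chrom"],
                strand=row["strand"],
                exon=(coords["exon_start"], coords["exon_end"]),
                upstream_intron=(coords["upstream_intron_start"], coords["upstream_intron_end"]),
                downstream_intron=(coords["downstream_intron_start"], coords["downstream_intron_end"]),
                regulation=regulation,
                delta_psi=float(dpsi_raw) if dpsi_raw else None,
            ))
    return events


def events_to_bed(events: Sequence[CassetteExonEvent], path) -> None:
    """Export exon intervals as 6-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for ev in events:
            score = "0" if ev.delta_psi is None else f"{ev.delta_psi:.4f}"
            fh.write(
                f"{ev.chrom}\t{ev.exon[0]}\t{ev.exon[1]}\t{ev.event_id}\t{score}\t{ev.strand}\n"
            )
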