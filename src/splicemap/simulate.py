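"""Seeded synthetic data with the statistical structure the pipeline assumes.

The generator emulates, at desk scale, every input the analysis consumes:

* a genome (one contig per gene) and GTF gene models in which each gene has
  an inclusion transcript (five exons) and a skipping transcript lacking the
  middle exon, so the middle exon is a single cassette exon and the two
  other internal exons are constitutive;
* splice sites drawn from donor/acceptor consensus frequency matrices by
  Boltzmann sampling at a class-specific temperature — regulated exons are
  sampled hotter (weaker) than reference cassette exons, which are hotter
  than constitutive exons — and class-specific flanking-intron GC;
* a degenerate motif planted into regulated sequences at a high rate and
  into reference sequences at a background rate, with a positional bias
  (downstream intron for depletion-down-regulated exons, upstream intron or
  exon for up-regulated ones); chance occurrences of the motif are scrubbed
  from the background so the planted rate is the observed rate;
* a patient cohort whose event PSI values come from a logistic transform of
  a Gaussian copula tied to a regulator RBP's expression (the monotone link
  preserves the target Spearman rho), with a subtype PSI shift, and
  survival times whose hazard depends on the PSI stratum of a designated
  prognostic event.

Everything is a deterministic function of the seed; ground truth is written
to a manifest so recovery tests can check every module against it.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exons import CassetteExonEvent, reverse_complement, write_event_table
from .motifs import IUPAC, count_motif_occurrences
from .nomination import iupac_to_ppm
from .cohort import CohortMatrix

NUCS = "ACGT"

# Donor consensus (3 exonic + 6 intronic, MAG|GTRAGT-like) and acceptor
# consensus (20 intronic + 3 exonic, pyrimidine tract + yAG|G-like)
# frequency matrices, loosely modelled on vertebrate splice-site logos.
DONOR_FREQS = np.array([
    [0.33, 0.36, 0.18, 0.13],
    [0.60, 0.13, 0.14, 0.13],
    [0.09, 0.04, 0.80, 0.07],
    [0.001, 0.001, 0.997, 0.001],
    [0.001, 0.001, 0.001, 0.997],
    [0.52, 0.03, 0.42, 0.03],
    [0.71, 0.08, 0.12, 0.09],
    [0.07, 0.06, 0.81, 0.06],
    [0.16, 0.15, 0.19, 0.50],
])
_PY = [0.09, 0.31, 0.10, 0.50]  # pyrimidine-tract position
# last 20 intronic: 17 pyrimidine positions, then y, A, G; first 3 exonic: mild G bias
ACCEPTOR_FREQS = np.array(
    [_PY] * 17
    + [
        [0.06, 0.40, 0.04, 0.50],   # y
        [0.997, 0.001, 0.001, 0.001],  # branch-site-proximal A of the yAG
        [0.001, 0.001, 0.997, 0.001],  # terminal G
        [0.25, 0.20, 0.35, 0.20],
        [0.25, 0.25, 0.25, 0.25],
        [0.25, 0.25, 0.25, 0.25],
    ]
)


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    seed: int = 0
    # gene structure
    n_regulated_up: int = 48
    n_regulated_down: int = 91
    n_reference_genes: int = 400
    exon_len_range: tuple[int, int] = (80, 200)
    intron_len_range: tuple[int, int] = (300, 500)
    pad_len: int = 150
    # splice-site weakness (Boltzmann sampling temperature; higher = weaker)
    temp_regulated: float = 2.0
    temp_reference_cassette: float = 1.3
    temp_constitutive: float = 1.0
    # composition
    gc_exon: float = 0.50
    gc_intron_regulated: float = 0.35
    gc_intron_reference: float = 0.45
    # motif planting
    motif_word: str = "CATGCAD"
    plant_rate_pos: float = 0.65
    plant_rate_neg: float = 0.10
    positional_bias: dict = field(default_factory=lambda: {
        "up": "upstream_or_exon", "down": "downstream",
        "reference_cassette": "none", "reference_constitutive": "none",
    })
    flank_len: int = 250
    delta_psi_range: tuple[float, float] = (0.1, 0.6)
    # cohort
    n_samples: int = 100
    rbp_name: str = "RBFOX2"
    regulator_gene: str = "NEK2"
    regulator_rbp_r: float = 0.6
    n_decoy_rbps: int = 10
    true_rho: float = 0.5
    group_delta_psi: float = 0.3
    frac_tnbc: float = 0.5
    hazard_ratio: float = 3.0
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    censoring_rate: float = 0.1

    def __post_init__(self):
        for name in ("plant_rate_pos", "plant_rate_neg", "gc_exon",
                     "gc_intron_regulated", "gc_intron_reference",
                     "frac_tnbc", "censoring_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("temp_regulated", "temp_reference_cassette",
                     "temp_constitutive", "hazard_ratio", "baseline_hazard"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if len(self.motif_word) > min(self.flank_len,
                                      self.intron_len_range[0] - 26):
            raise ValueError("motif_word does not fit inside a flank")
        for letter in self.motif_word:
            if letter not in IUPAC:
                raise ValueError(f"invalid IUPAC letter {letter!r} in motif_word")


def boltzmann_sample(freqs: np.ndarray, temperature: float, rng) -> str:
    """Sample one letter per position with probability ∝ f^(1/T)."""
    out = []
    for row in freqs:
        p = row ** (1.0 / temperature)
        p = p / p.sum()
        out.append(NUCS[rng.choice(4, p=p)])
    return "".join(out)


def _background(length: int, gc: float, rng) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return [NUCS[i] for i in rng.choice(4, size=length, p=p)]


def _concrete_motif(word: str, rng) -> str:
    return "".join(IUPAC[c][rng.integers(len(IUPAC[c]))] for c in word)


def _scrub(chars: list[str], word: str, gc: float, rng,
           protected: list[tuple[int, int]], max_rounds: int = 50) -> None:
    """Rewrite chance motif matches from the background distribution.

    Spans overlapping a protected interval (splice-site windows, planted
    instances) are left alone.
    """
    w = len(word)
    for _ in range(max_rounds):
        seq = "".join(chars)
        _, offsets = count_motif_occurrences(seq, word)
        dirty = [
            off for off in offsets
            if not any(off < b and off + w > a for a, b in protected)
        ]
        if not dirty:
            return
        for off in dirty:
            chars[off:off + w] = _background(w, gc, rng)


@dataclass
class SyntheticGene:
    gene_id: str
    strand: str
    contig_seq: str
    exons_sense: list[tuple[int, int]]   # sense-strand coordinates, 5'->3'
    event: CassetteExonEvent | None
    group: str
    planted: bool
    plant_region: str | None
    plant_offset: int | None             # sense coordinate of the instance


def _sense_to_genomic(iv: tuple[int, int], total: int, strand: str) -> tuple[int, int]:
    if strand == "+":
        return iv
    return total - iv[1], total - iv[0]


def _build_gene(gene_id: str, group: str, cfg: SimulationConfig, rng) -> SyntheticGene:
    exon_lens = [int(rng.integers(*cfg.exon_len_range)) for _ in range(5)]
    intron_lens = [int(rng.integers(*cfg.intron_len_range)) for _ in range(4)]
    gc_flank = (cfg.gc_intron_regulated if group in ("up", "down")
                else cfg.gc_intron_reference)

    # sense-strand layout: pad exon0 i0 exon1 i1 exon2 i2 exon3 i3 exon4 pad
    segments = []
    coords = []
    pos = cfg.pad_len
    segments.append(_background(cfg.pad_len, cfg.gc_intron_reference, rng))
    for i in range(5):
        coords.append((pos, pos + exon_lens[i]))
        segments.append(_background(exon_lens[i], cfg.gc_exon, rng))
        pos += exon_lens[i]
        if i < 4:
            gc = gc_flank if i in (1, 2) else cfg.gc_intron_reference
            segments.append(_background(intron_lens[i], gc, rng))
            pos += intron_lens[i]
    segments.append(_background(cfg.pad_len, cfg.gc_intron_reference, rng))
    chars = [c for seg in segments for c in seg]
    total = len(chars)

    if group in ("up", "down"):
        cassette_temp = cfg.temp_regulated
    elif group == "reference_cassette":
        cassette_temp = cfg.temp_reference_cassette
    else:
        cassette_temp = cfg.temp_constitutive

    protected: list[tuple[int, int]] = []
    for i in range(5):
        s, e = coords[i]
        if i < 4:  # donor at exon i / intron i junction
            temp = cassette_temp if i == 2 else cfg.temp_constitutive
            site = boltzmann_sample(DONOR_FREQS, temp, rng)
            chars[e - 3:e + 6] = list(site)
            protected.append((e - 3, e + 6))
        if i > 0:  # acceptor at intron i-1 / exon i junction
            temp = cassette_temp if i == 2 else cfg.temp_constitutive
            site = boltzmann_sample(ACCEPTOR_FREQS, temp, rng)
            chars[s - 20:s + 3] = list(site)
            protected.append((s - 20, s + 3))

    # plant the motif into the cassette-exon neighbourhood
    plant_rate = (cfg.plant_rate_pos if group in ("up", "down")
                  else cfg.plant_rate_neg)
    bias = cfg.positional_bias.get(group, "none")
    planted = bool(rng.random() < plant_rate)
    plant_region = plant_offset = None
    cs, ce = coords[2]
    i1s, i1e = coords[1][1], cs   # upstream intron (sense)
    i2s, i2e = ce, coords[3][0]   # downstream intron (sense)
    regions = {
        # windows that extract_event_sequences will report, minus the
        # splice-site windows at their edges
        "upstream_intron": (max(i1s + 6, cs - cfg.flank_len), cs - 20),
        "exon": (cs + 3, ce - 3),
        "downstream_intron": (ce + 6, min(i2e - 20, ce + cfg.flank_len)),
    }
    if planted:
        if bias == "downstream":
            region = "downstream_intron"
        elif bias == "upstream_or_exon":
            region = "upstream_intron" if rng.random() < 0.5 else "exon"
        else:
            region = ("upstream_intron", "exon", "downstream_intron")[rng.integers(3)]
        a, b = regions[region]
        w = len(cfg.motif_word)
        off = int(rng.integers(a, b - w + 1))
        chars[off:off + w] = list(_concrete_motif(cfg.motif_word, rng))
        protected.append((off, off + w))
        plant_region, plant_offset = region, off

    _scrub(chars, cfg.motif_word, cfg.gc_intron_reference, rng, protected)

    strand = "+" if rng.random() < 0.5 else "-"
    sense_seq = "".join(chars)
    contig_seq = sense_seq if strand == "+" else reverse_complement(sense_seq)

    exon_g = _sense_to_genomic(coords[2], total, strand)
    up_g = _sense_to_genomic((i1s, i1e), total, strand)
    down_g = _sense_to_genomic((i2s, i2e), total, strand)
    is_regulated = group in ("up", "down")
    dpsi = None
    if is_regulated:
        mag = rng.uniform(*cfg.delta_psi_range)
        dpsi = float(mag if group == "up" else -mag)
    event = CassetteExonEvent(
        event_id=f"{gene_id}:{gene_id}:{exon_g[0]}-{exon_g[1]}",
        gene_id=gene_id,
        chrom=gene_id,
        strand=strand,
        exon=exon_g,
        upstream_intron=up_g,
        downstream_intron=down_g,
        regulation=group,
        delta_psi=dpsi,
    ) if is_regulated else None
    return SyntheticGene(gene_id, strand, contig_seq, coords, event, group,
                         planted, plant_region, plant_offset)


@dataclass
class ReferenceBundle:
    genome_path: Path
    gtf_path: Path
    regulated_table: Path
    manifest_path: Path
    regulated_events: list[CassetteExonEvent]
    genes: list[SyntheticGene]
    manifest: dict


def generate_reference(config: SimulationConfig, outdir) -> ReferenceBundle:
    """Write genome FASTA + GTF + regulated event table + truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    plan = (
        [("down", i) for i in range(config.n_regulated_down)]
        + [("up", i) for i in range(config.n_regulated_up)]
        + [("reference", i) for i in range(config.n_reference_genes)]
    )
    genes: list[SyntheticGene] = []
    for group, i in plan:
        gene_id = f"{group.upper()[:3]}{i:04d}"
        build_group = group if group != "reference" else "reference_cassette"
        genes.append(_build_gene(gene_id, build_group, config, rng))

    genome_path = outdir / "genome.fa"
    with open(genome_path, "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_id}\n")
            for i in range(0, len(g.contig_seq), 60):
                fh.write(g.contig_seq[i:i + 60] + "\n")

    gtf_path = outdir / "annotation.gtf"
    with open(gtf_path, "w") as fh:
        for g in genes:
            total = len(g.contig_seq)
            for tx, keep in (("t1", None), ("t2", 2)):
                tx_id = f"{g.gene_id}.{tx}"
                for i, iv in enumerate(g.exons_sense):
                    if keep is not None and i == keep:
                        continue
                    gs, ge = _sense_to_genomic(iv, total, g.strand)
                    fh.write(
                        f"{g.gene_id}\tsplicemap_sim\texon\t{gs + 1}\t{ge}\t.\t"
                        f"{g.strand}\t.\t"
                        f'gene_id "{g.gene_id}"; transcript_id "{tx_id}";\n'
                    )

    regulated = [g.event for g in genes if g.event is not None]
    regulated_table = outdir / "events_regulated.tsv"
    write_event_table(regulated, regulated_table)

    manifest = {
        "seed": config.seed,
        "motif_word": config.motif_word,
        "genes": {
            g.gene_id: {
                "group": g.group,
                "strand": g.strand,
                "planted": g.planted,
                "plant_region": g.plant_region,
                "plant_offset_sense": g.plant_offset,
                "event_id": g.event.event_id if g.event else None,
                "delta_psi": g.event.delta_psi if g.event else None,
            }
            for g in genes
        },
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return ReferenceBundle(genome_path, gtf_path, regulated_table,
                           manifest_path, regulated, genes, manifest)


def generate_motif_sets(
    n_pos: int = 150, n_neg: int = 1000,
    plant_rate_pos: float = 0.65, plant_rate_neg: float = 0.10,
    word: str = "CATGCA", seq_len: int = 600, gc: float = 0.45,
    seed: int = 0,
):
    """Raw positive/negative sequence sets with exact planted presence rates.

    Background occurrences of the word are scrubbed, so a sequence contains
    a match iff it received a planted instance.  Returns
    (pos_seqs, neg_seqs, manifest).
    """
    rng = np.random.default_rng(seed)
    manifest = {"pos_planted": [], "neg_planted": []}

    def make(n, rate, key):
        seqs = []
        for _ in range(n):
            chars = _background(seq_len, gc, rng)
            planted = bool(rng.random() < rate)
            if planted:
                off = int(rng.integers(0, seq_len - len(word) + 1))
                chars[off:off + len(word)] = list(_concrete_motif(word, rng))
                _scrub(chars, word, gc, rng, [(off, off + len(word))])
            else:
                _scrub(chars, word, gc, rng, [])
            manifest[key].append(planted)
            seqs.append("".join(chars))
        return seqs

    pos = make(n_pos, plant_rate_pos, "pos_planted")
    neg = make(n_neg, plant_rate_neg, "neg_planted")
    return pos, neg, manifest


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula Pearson parameter giving target Spearman rho."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def generate_cohort(config: SimulationConfig, events,
                    differential_events=None, survival_event=None):
    """Simulate a patient cohort tied to the regulated events.

    ``events`` may be CassetteExonEvent objects or (event_id, regulation)
    pairs.  PSI for each event follows a logistic transform of a latent
    Gaussian correlated with the regulator RBP's expression at the target
    Spearman rho (positive for depletion-down-regulated events, negative
    for up-regulated ones).  TNBC samples get a ``group_delta_psi`` PSI
    shift on the designated differential events (all events by default).
    Survival times are exponential, with the hazard multiplied by
    ``hazard_ratio`` for patients with PSI > 0.5 on the designated
    prognostic event (the first event by default).

    Returns (CohortMatrix, manifest).
    """
    if config.n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    items = []
    for ev in events:
        if hasattr(ev, "event_id"):
            items.append((ev.event_id, ev.regulation))
        else:
            items.append((ev[0], ev[1]))
    if not items:
        raise ValueError("no events supplied")
    event_ids = [e for e, _ in items]
    if differential_events is None:
        differential_events = set(event_ids)
    else:
        differential_events = set(differential_events)
    if survival_event is None:
        survival_event = event_ids[0]

    rng = np.random.default_rng(config.seed + 1_000_003)
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    n_tnbc = int(round(config.frac_tnbc * n))
    subtype = np.array(["TNBC"] * n_tnbc + ["OtherBC"] * (n - n_tnbc))
    rng.shuffle(subtype)

    z_rbp = rng.standard_normal(n)
    rho_p_reg = spearman_to_pearson(config.regulator_rbp_r)
    z_regulator = rho_p_reg * z_rbp + math.sqrt(1 - rho_p_reg ** 2) * rng.standard_normal(n)

    expr_rows = {
        config.rbp_name: 8.0 + 1.5 * z_rbp,
        config.regulator_gene: 8.0 + 1.5 * z_regulator,
    }
    for i in range(config.n_decoy_rbps):
        expr_rows[f"DECOY_{i:02d}"] = 8.0 + 1.5 * rng.standard_normal(n)
    expression = pd.DataFrame(expr_rows, index=samples).T

    rho_p = spearman_to_pearson(abs(config.true_rho))
    psi_rows = {}
    truth_rho = {}
    for event_id, regulation in items:
        sign = 1.0 if regulation == "down" else -1.0
        rho_signed = sign * abs(config.true_rho)
        truth_rho[event_id] = rho_signed
        z = sign * rho_p * z_rbp + math.sqrt(1 - rho_p ** 2) * rng.standard_normal(n)
        if event_id == survival_event:
            # near-uniform PSI spread so every stratum boundary is populated
            mu, scale = 0.0, 1.702
        else:
            mu, scale = float(rng.normal(-0.4, 0.3)), 1.0
        psi = _logistic(mu + scale * z)
        if event_id in differential_events and config.group_delta_psi != 0:
            # the kinase promotes the TNBC-specific variant: exons it
            # up-regulates sit higher in TNBC, down-regulated ones lower
            shift = config.group_delta_psi * (1.0 if regulation == "up" else -1.0)
            psi = np.where(subtype == "TNBC",
                           np.clip(psi + shift, 0, 1), psi)
        psi_rows[event_id] = psi
    psi = pd.DataFrame(psi_rows, index=samples).T

    surv_psi = psi.loc[survival_event].to_numpy()
    high = surv_psi > 0.5
    rate = config.baseline_hazard * np.where(high, config.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / rate)
    # independent exponential censoring; its rate is calibrated so that the
    # expected censored fraction equals censoring_rate
    r = config.censoring_rate
    if r >= 1.0:
        t_obs = rng.exponential(1.0 / rate.mean(), size=n)
        indicator = np.zeros(n, dtype=int)
    else:
        if r > 0:
            c_rate = rate.mean() * r / (1.0 - r)
            t_cens = rng.exponential(1.0 / c_rate, size=n)
        else:
            t_cens = np.full(n, np.inf)
        indicator = (t_event <= t_cens).astype(int)
        t_obs = np.minimum(t_event, t_cens)
    t_obs = np.maximum(t_obs, 1e-3)

    meta = pd.DataFrame({
        "subtype": subtype,
        "survival_time": t_obs,
        "event_indicator": indicator,
    }, index=samples)
    manifest = {
        "true_rho": truth_rho,
        "differential_events": sorted(differential_events),
        "survival_event": survival_event,
        "high_stratum_cutoff": 0.5,
        "hazard_ratio": config.hazard_ratio,
    }
    return CohortMatrix(psi=psi, expression=expression, sample_meta=meta), manifest


def write_cohort(cohort: CohortMatrix, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "psi": outdir / "psi.tsv",
        "expression": outdir / "expression.tsv",
        "sample_meta": outdir / "sample_meta.tsv",
    }
    cohort.psi.to_csv(paths["psi"], sep="\t")
    cohort.expression.to_csv(paths["expression"], sep="\t")
    cohort.sample_meta.to_csv(paths["sample_meta"], sep="\t")
    return paths


def write_compendium(config: SimulationConfig, path, n_decoys: int | None = None):
    """Write a MEME-minimal compendium: the planted RBP's motif + decoys."""
    rng = np.random.default_rng(config.seed + 7_777)
    n_decoys = config.n_decoy_rbps if n_decoys is None else n_decoys
    entries = [(config.rbp_name, iupac_to_ppm(config.motif_word))]
    for i in range(n_decoys):
        width = int(rng.integers(5, 9))
        ppm = rng.dirichlet([0.6] * 4, size=width)
        entries.append((f"DECOY_{i:02d}", ppm))
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for name, ppm in entries:
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(ppm)} "
                     f"nsites= 20 E= 0\n")
            for row in ppm:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")
    return Path(path)
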