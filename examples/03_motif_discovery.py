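"""Discriminative motif discovery and the positional RNA map.

Finds the sequence element enriched in regulated exons and their flanking
introns versus the reference sets, then maps where its occurrences sit on
a meta-exon axis (250 nt intron flanks + scaled exon body).
"""

from pathlib import Path

import numpy as np
from pyfaidx import Fasta

from splicemap import (
    SimulationConfig,
    build_reference_sets,
    discover_motifs,
    extract_event_sequences,
    generate_reference,
    load_gene_models,
    motif_presence_stats,
    positional_profile,
)

cfg = SimulationConfig(seed=42)
bundle = generate_reference(cfg, Path("example_out/inputs"))
genome = Fasta(str(bundle.genome_path))
models = load_gene_models(bundle.gtf_path)
cassette, constitutive = build_reference_sets(
    models, {m.gene_id for m in models}, bundle.regulated_events)

seqs = {}
for name, events in (("up", [e for e in bundle.regulated_events if e.regulation == "up"]),
                     ("down", [e for e in bundle.regulated_events if e.regulation == "down"]),
                     ("ref_cassette", cassette),
                     ("ref_constitutive", constitutive)):
    seqs[name] = [extract_event_sequences(genome, e, cfg.flank_len) for e in events]

pos = [s.concatenated() for s in seqs["up"] + seqs["down"]]
neg = [s.concatenated() for s in seqs["ref_cassette"] + seqs["ref_constitutive"]]
(motif, *_rest) = discover_motifs(pos, neg, max_motifs=1)
print(f"top motif      : {motif.iupac_word}  (Fisher p = {motif.p_value:.2e}, "
      f"E = {motif.e_value:.2e})")

table, chi2_p, _ = motif_presence_stats(
    {k: [s.concatenated() for s in v] for k, v in seqs.items()}, motif.iupac_word)
print(table.round(3).to_string(index=False))
print(f"chi-square p   : {chi2_p:.2e}")

for direction in ("up", "down"):
    prof = positional_profile(seqs[direction], motif.iupac_word)
    peak = int(np.argmax(prof.density))
    print(f"{direction:>4}-regulated profile peak: {prof.region_of(peak)}")
# Down-regulated-on-depletion exons carry the motif downstream of the 5'ss,
# up-regulated ones upstream or within the exon: a position-dependent RNA
# map typical of activator/repressor splicing factors.
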