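"""End-to-end orchestration of the cassette-exon analysis.

Stages run in a fixed order — reference sets, sequence extraction, splice
model, sequence features, motif discovery, presence/positional statistics,
compendium matching, PSI-expression concordance, cohort differential
statistics, survival stratification — and each writes a self-describing TSV
(header plus a '#' provenance line carrying the config hash).  A summary
JSON collects the headline results; it is a deterministic function of the
inputs and the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pyfaidx import Fasta

from . import cohort as cohort_mod
from . import exons, features, motifs, nomination

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    genome: str
    gtf: str
    regulated_events: str
    outdir: str = "splicemap_out"
    psi: str | None = None
    expression: str | None = None
    sample_meta: str | None = None
    compendium: str | None = None
    # thresholds
    delta_psi_threshold: float = 0.1
    fdr_threshold: float = 0.01
    motif_e_threshold: float = 0.05
    alpha: float = 0.05
    # geometry / smoothing
    flank_len: int = 250
    exon_bins: int = 100
    profile_sigma: float = 10.0
    # scope knobs
    max_motifs: int = 3
    max_survival_events: int = 20
    n_permutations: int = 200
    regulator_effect: str = "positive"
    seed: int = 0

    def __post_init__(self):
        for name in ("genome", "gtf", "regulated_events"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        for name in ("psi", "expression", "sample_meta", "compendium"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        for name, lo, hi in (("delta_psi_threshold", 0, 1), ("fdr_threshold", 0, 1),
                             ("motif_e_threshold", 0, float("inf")), ("alpha", 0, 1)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} out of range")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, stage: str, cfg_hash: str):
    with open(path, "w") as fh:
        fh.write(f"# splicemap stage={stage} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the summary dict (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("splicemap")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"config": cfg_hash, "seed": config.seed}
    stage = "load"
    try:
        genome = Fasta(str(config.genome))
        models = exons.load_gene_models(config.gtf)
        regulated = exons.read_event_table(config.regulated_events)
        root.info("loaded %d gene models, %d regulated events",
                  len(models), len(regulated))

        stage = "refsets"
        expressed = {m.gene_id for m in models}
        ref_cassette, ref_constitutive = exons.build_reference_sets(
            models, expressed, regulated)
        groups = {
            "up": [e for e in regulated if e.regulation == "up"],
            "down": [e for e in regulated if e.regulation == "down"],
            "reference_cassette": ref_cassette,
            "reference_constitutive": ref_constitutive,
        }
        exons.write_event_table(ref_cassette, outdir / "reference_cassette.tsv")
        exons.write_event_table(ref_constitutive, outdir / "reference_constitutive.tsv")
        summary["n_events"] = {k: len(v) for k, v in groups.items()}

        stage = "sequences"
        seqs = {
            name: [exons.extract_event_sequences(genome, e, config.flank_len)
                   for e in evs]
            for name, evs in groups.items()
        }

        stage = "splice_model"
        model = features.train_splice_site_model(ref_constitutive, genome)

        stage = "features"
        records = []
        for name, evs in groups.items():
            for e in evs:
                records.append(features.compute_event_features(
                    e, genome, model, group=name))
        feat_df = features.features_to_frame(records)
        _write_table(feat_df, outdir / "features.tsv", "features", cfg_hash)
        tests = features.compare_feature_groups(feat_df)
        _write_table(tests, outdir / "feature_tests.tsv", "features", cfg_hash)

        stage = "motifs"
        pos = [s.concatenated() for s in seqs["up"] + seqs["down"]]
        neg = [s.concatenated()
               for s in seqs["reference_cassette"] + seqs["reference_constitutive"]]
        found = motifs.discover_motifs(
            pos, neg, e_threshold=config.motif_e_threshold,
            max_motifs=config.max_motifs)
        motif_df = pd.DataFrame([dataclasses.asdict(m) for m in found])
        _write_table(motif_df, outdir / "motifs.tsv", "motifs", cfg_hash)
        top_motif = found[0].iupac_word if found else None
        summary["top_motif"] = top_motif

        if top_motif:
            stage = "motif_stats"
            table, chi2_p, pairwise = motifs.motif_presence_stats(
                {k: [s.concatenated() for s in v] for k, v in seqs.items()},
                top_motif)
            _write_table(table, outdir / "motif_presence.tsv", "motif_stats", cfg_hash)
            _write_table(pairwise, outdir / "motif_count_tests.tsv", "motif_stats", cfg_hash)
            summary["presence_chi2_p"] = chi2_p

            stage = "profiles"
            profiles = {
                name: motifs.positional_profile(
                    seqs[name], top_motif, flank_len=config.flank_len,
                    exon_bins=config.exon_bins, sigma=config.profile_sigma)
                for name in groups
            }
            prof_df = pd.DataFrame({
                name: prof.density for name, prof in profiles.items()
            })
            prof_df.insert(0, "meta_position", np.arange(len(prof_df)))
            _write_table(prof_df, outdir / "profiles.tsv", "profiles", cfg_hash)
            consistency = nomination.positional_consistency(
                {d: profiles[d] for d in ("up", "down") if d in profiles})
            summary["positional_consistency"] = {
                d: v.get("verdict") for d, v in consistency.items()
            }
            summary["profile_peaks"] = {
                d: v.get("peak_region") for d, v in consistency.items()
            }

        top_rbp = None
        if top_motif and config.compendium:
            stage = "compendium"
            compendium = nomination.read_meme_compendium(config.compendium)
            matches = nomination.match_motif_to_compendium(
                nomination.iupac_to_ppm(top_motif), compendium,
                n_permutations=config.n_permutations, seed=config.seed)
            match_df = pd.DataFrame([dataclasses.asdict(m) for m in matches])
            _write_table(match_df, outdir / "compendium_matches.tsv",
                         "compendium", cfg_hash)
            top_rbp = matches[0].rbp_name
            summary["top_rbp"] = top_rbp
            summary["top_rbp_similarity"] = matches[0].similarity

        have_cohort = all(
            getattr(config, k) for k in ("psi", "expression", "sample_meta"))
        if not have_cohort:
            root.info("cohort matrices not provided; cohort stages skipped")
            summary["cohort"] = "skipped"
        else:
            stage = "cohort_load"
            psi = pd.read_csv(config.psi, sep="\t", index_col=0)
            expression = pd.read_csv(config.expression, sep="\t", index_col=0)
            meta = pd.read_csv(config.sample_meta, sep="\t", index_col=0)

            if top_rbp:
                stage = "concordance"
                rbp_list = [top_rbp] if top_rbp in expression.index else []
                recs = nomination.correlate_psi_expression(
                    psi, expression, rbp_list,
                    groups["up"] + groups["down"])
                recs, conc_summary = nomination.classify_concordance(
                    recs, alpha=config.alpha,
                    regulator_effect=config.regulator_effect)
                conc_df = pd.DataFrame([dataclasses.asdict(r) for r in recs])
                _write_table(conc_df, outdir / "concordance.tsv",
                             "concordance", cfg_hash)
                _write_table(conc_summary, outdir / "concordance_summary.tsv",
                             "concordance", cfg_hash)
                row = conc_summary[conc_summary.rbp_name == top_rbp]
                if len(row):
                    summary["fraction_concordant"] = float(
                        row.iloc[0]["fraction_concordant"])

            stage = "differential_psi"
            labels = meta["subtype"]
            groups_order = None
            if set(labels.unique()) == {"TNBC", "OtherBC"}:
                groups_order = ("TNBC", "OtherBC")
            diff = cohort_mod.differential_psi(
                psi, labels,
                delta_threshold=config.delta_psi_threshold,
                fdr_threshold=config.fdr_threshold,
                groups=groups_order)
            diff_df = pd.DataFrame([dataclasses.asdict(d) for d in diff])
            _write_table(diff_df, outdir / "differential_psi.tsv",
                         "differential_psi", cfg_hash)
            significant = {d.event_id for d in diff if d.significant}
            summary["n_significant_differential"] = len(significant)

            stage = "overlap"
            universe = set(psi.index)
            regulated_in_universe = {
                e.event_id for e in regulated if e.event_id in universe}
            k, p = cohort_mod.overlap_test(
                regulated_in_universe, significant, universe)
            summary["overlap"] = {"count": k, "p_value": p}

            stage = "direction_agreement"
            shared = []
            diff_by_id = {d.event_id: d for d in diff if d.significant}
            for e in regulated:
                d = diff_by_id.get(e.event_id)
                if d is None or e.regulation not in ("up", "down"):
                    continue
                dir_b = "up" if d.delta_median_psi > 0 else "down"
                shared.append((e.regulation, dir_b))
            if shared:
                table, fisher_p, frac = cohort_mod.direction_agreement_test(shared)
                summary["direction_agreement"] = {
                    "n": len(shared), "fisher_p": fisher_p,
                    "fraction_agreeing": frac,
                }

            stage = "survival"
            surv_rows = []
            usable = meta.dropna(subset=["survival_time", "event_indicator"])
            candidates = [d.event_id for d in diff if d.tested]
            for event_id in candidates[:config.max_survival_events]:
                row = psi.loc[event_id, usable.index]
                try:
                    import warnings as _warnings
                    with _warnings.catch_warnings():
                        _warnings.simplefilter("ignore", UserWarning)
                        strat = cohort_mod.km_stratify(
                            row.to_numpy(dtype=float),
                            usable["survival_time"].to_numpy(dtype=float),
                            usable["event_indicator"].to_numpy(dtype=float),
                            cutoff_mode="optimal", event_id=event_id)
                except ValueError as exc:
                    root.info("survival skipped for %s: %s", event_id, exc)
                    continue
                surv_rows.append({
                    "event_id": event_id, "psi_cutoff": strat.psi_cutoff,
                    "n_high": strat.n_high, "n_low": strat.n_low,
                    "logrank_stat": strat.logrank_stat, "p_value": strat.p_value,
                })
            surv_df = pd.DataFrame(surv_rows)
            _write_table(surv_df, outdir / "survival.tsv", "survival", cfg_hash)
            if surv_rows:
                n_prog = sum(1 for r in surv_rows if r["p_value"] <= config.alpha)
                summary["n_prognostic_events"] = n_prog
    except PipelineStageError:
        raise
    except Exception as exc:
        root.removeHandler(handler)
        handler.close()
        raise PipelineStageError(stage, exc) from exc

    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1)
    root.removeHandler(handler)
    handler.close()
    return summary
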