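"""Compendium matching, concordance classification and RNA-map consistency."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splicemap.motifs import PositionalProfile
from splicemap.nomination import (
    CompendiumMotif,
    ConcordanceRecord,
    classify_concordance,
    correlate_gene_pair,
    correlate_psi_expression,
    iupac_to_ppm,
    match_motif_to_compendium,
    positional_consistency,
    read_meme_compendium,
    spearman_with_p,
)


def test_iupac_to_ppm_columns():
    ppm = iupac_to_ppm("AND")
    assert ppm[0].tolist() == [1, 0, 0, 0]
    assert ppm[1].tolist() == [0.25, 0.25, 0.25, 0.25]
    assert ppm[2] == pytest.approx([1 / 3, 0, 1 / 3, 1 / 3])
    with pytest.raises(ValueError):
        iupac_to_ppm("AXZ")


def test_compendium_round_trip_through_meme(tmp_path, small_bundle):
    from splicemap.simulate import write_compendium
    cfg, _ = small_bundle
    path = write_compendium(cfg, tmp_path / "comp.meme")
    comp = read_meme_compendium(path)
    names = [c.rbp_name for c in comp]
    assert cfg.rbp_name in names
    planted = next(c for c in comp if c.rbp_name == cfg.rbp_name)
    assert planted.ppm == pytest.approx(iupac_to_ppm(cfg.motif_word), abs=1e-4)


def test_rna_alphabet_u_mapped_to_t(tmp_path):
    text = (
        "MEME version 4\n\nALPHABET= ACGU\n\nstrands: +\n\n"
        "Background letter frequencies\nA 0.25 C 0.25 G 0.25 U 0.25\n\n"
        "MOTIF UONLY\nletter-probability matrix: alength= 4 w= 4 nsites= 20 E= 0\n"
        + "0.0 0.0 0.0 1.0\n" * 4
    )
    path = tmp_path / "rna.meme"
    path.write_text(text)
    (motif,) = read_meme_compendium(path)
    # all mass on T (index 3 of ACGT)
    assert motif.ppm[:, 3] == pytest.approx(np.ones(4))


def test_identical_motif_ranks_first_with_similarity_one():
    rng = np.random.default_rng(2)
    query = iupac_to_ppm("CATGCAD")
    comp = [CompendiumMotif("TARGET", query.copy())]
    for i in range(5):
        comp.append(CompendiumMotif(f"D{i}", rng.dirichlet([1] * 4, size=7)))
    matches = match_motif_to_compendium(query, comp, n_permutations=50, seed=0)
    assert matches[0].rbp_name == "TARGET"
    assert matches[0].similarity == pytest.approx(1.0)
    assert matches[0].offset == 0


def test_subwindow_alignment_found():
    rng = np.random.default_rng(4)
    target = rng.dirichlet([1] * 4, size=12)
    query = target[3:9].copy()
    comp = [CompendiumMotif("T", target)]
    matches = match_motif_to_compendium(query, comp, n_permutations=10, seed=0)
    assert matches[0].offset == 3
    assert matches[0].similarity == pytest.approx(1.0)


def test_empty_compendium_rejected():
    with pytest.raises(ValueError):
        match_motif_to_compendium(iupac_to_ppm("CATG"), [], seed=0)


def test_permutation_p_reproducible_and_seed_sensitive():
    rng = np.random.default_rng(6)
    query = iupac_to_ppm("CATGCA")
    comp = [CompendiumMotif(f"T{i}", rng.dirichlet([1] * 4, size=8))
            for i in range(4)]
    a = match_motif_to_compendium(query, comp, n_permutations=99, seed=5)
    b = match_motif_to_compendium(query, comp, n_permutations=99, seed=5)
    c = match_motif_to_compendium(query, comp, n_permutations=99, seed=6)
    assert [m.p_value for m in a] == [m.p_value for m in b]
    assert any(x.p_value != y.p_value for x, y in
               zip(sorted(a, key=lambda m: m.rbp_name),
                   sorted(c, key=lambda m: m.rbp_name)))


def test_null_permutation_p_roughly_uniform():
    rng = np.random.default_rng(8)
    query = rng.dirichlet([1] * 4, size=6)
    comp = [CompendiumMotif(f"T{i}", rng.dirichlet([1] * 4, size=8))
            for i in range(80)]
    matches = match_motif_to_compendium(query, comp, n_permutations=99, seed=1)
    ks = stats.kstest([m.p_value for m in matches], "uniform")
    assert ks.pvalue > 0.01


def test_exact_spearman_p_matches_permutation_oracle():
    rng = np.random.default_rng(12)
    x = rng.normal(size=7)
    y = 0.7 * x + rng.normal(size=7)
    rho, p = spearman_with_p(x, y)
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    obs = abs(stats.spearmanr(x, y).statistic)
    count = total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, perm)[0, 1]
        count += abs(r) >= obs - 1e-12
        total += 1
    assert rho == pytest.approx(stats.spearmanr(x, y).statistic)
    assert p == pytest.approx(count / total)


def _cohort_frames():
    samples = [f"S{i}" for i in range(20)]
    x = np.linspace(0, 1, 20)
    psi = pd.DataFrame({s: [v, 0.5] for s, v in zip(samples, x)},
                       index=["evA", "evB"])
    expr = pd.DataFrame({s: [v * 2 + 1] for s, v in zip(samples, x)},
                        index=["RBP1"])
    return psi, expr


def test_monotone_psi_gives_rho_one():
    psi, expr = _cohort_frames()
    recs = correlate_psi_expression(psi, expr, ["RBP1"], [("evA", "down")])
    (rec,) = recs
    assert rec.rho == pytest.approx(1.0)
    assert rec.usable


def test_constant_psi_flagged_unusable():
    psi, expr = _cohort_frames()
    recs = correlate_psi_expression(psi, expr, ["RBP1"], [("evB", "down")])
    assert not recs[0].usable


def _rec(rho, p, regulation):
    return ConcordanceRecord("e", "RBP", rho, p, 50, regulation)


@pytest.mark.parametrize("rho,p,regulation,expected", [
    (0.6, 0.001, "down", True),    # positive correlation, down on depletion
    (-0.6, 0.001, "up", True),     # negative correlation, up on depletion
    (0.6, 0.001, "up", False),     # discordant
    (0.6, 0.2, "down", False),     # not significant
])
def test_concordance_rule(rho, p, regulation, expected):
    records, summary = classify_concordance([_rec(rho, p, regulation)])
    assert records[0].concordant is expected
    expected_sign = "+" if regulation == "down" else "-"
    assert records[0].expected_sign == expected_sign


def test_negative_regulator_effect_flips_rule():
    records, _ = classify_concordance([_rec(0.6, 0.001, "up")],
                                      regulator_effect="negative")
    assert records[0].concordant is True


def test_classification_is_idempotent():
    recs = [_rec(0.6, 0.001, "down"), _rec(-0.2, 0.3, "up")]
    once, _ = classify_concordance(recs)
    snapshot = [(r.expected_sign, r.concordant) for r in once]
    twice, _ = classify_concordance(once)
    assert [(r.expected_sign, r.concordant) for r in twice] == snapshot


def _profile(peak_region):
    flank, bins = 250, 100
    density = np.zeros(2 * flank + bins)
    idx = {"upstream_intron": 100, "exon": flank + 50,
           "downstream_intron": flank + bins + 80}[peak_region]
    density[idx] = 1.0
    return PositionalProfile(flank, bins, density.copy(), density, 10, 10)


def test_positional_consistency_matches_rna_map_rule():
    report = positional_consistency({
        "down": _profile("downstream_intron"),
        "up": _profile("upstream_intron"),
    })
    assert report["down"]["verdict"] == "consistent"
    assert report["up"]["verdict"] == "consistent"


def test_positional_inconsistency_flagged():
    report = positional_consistency({"down": _profile("upstream_intron")})
    assert report["down"]["verdict"] == "inconsistent"


def test_flat_profiles_report_no_signal():
    flank, bins = 250, 100
    zero = np.zeros(2 * flank + bins)
    prof = PositionalProfile(flank, bins, zero, zero, 10, 0)
    report = positional_consistency({"down": prof, "up": prof})
    assert report["down"]["verdict"] == "no_signal"
    assert report["up"]["verdict"] == "no_signal"


def test_gene_pair_correlation_extremes():
    samples = [f"S{i}" for i in range(10)]
    x = np.arange(10, dtype=float)
    expr = pd.DataFrame({s: [v, 2 * v, -v] for s, v in zip(samples, x)},
                        index=["A", "B", "C"])
    r, p = correlate_gene_pair(expr, "A", "B")
    assert r == pytest.approx(1.0)
    r, _ = correlate_gene_pair(expr, "A", "C")
    assert r == pytest.approx(-1.0)
    with pytest.raises(KeyError):
        correlate_gene_pair(expr, "A", "missing")
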