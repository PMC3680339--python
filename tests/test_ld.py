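"""Pairwise r², decay binning, window construction, and interval
annotation against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from rfgwas import annotate_windows, ld_decay, pairwise_r2, read_bed, read_gff3, snp_windows

from conftest import toy_genotypes


def test_r2_self_copy_is_one():
    rng = np.random.default_rng(0)
    col = rng.integers(0, 3, 40).astype(float)
    g = toy_genotypes(np.column_stack([col, col]))
    out = pairwise_r2(g)
    assert len(out) == 1
    assert out["r2"].iloc[0] == pytest.approx(1.0, abs=1e-12)


def test_r2_hand_calculation():
    """6-animal dosage pair against a hand Pearson correlation (1e-12)."""
    x = np.array([0, 1, 2, 1, 0, 2], dtype=float)
    y = np.array([1, 1, 2, 0, 0, 2], dtype=float)
    g = toy_genotypes(np.column_stack([x, y]))
    out = pairwise_r2(g)
    # hand calculation: r = cov(x, y) / (sd(x) sd(y))
    xm, ym = x - x.mean(), y - y.mean()
    r_hand = (xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym))
    assert out["r2"].iloc[0] == pytest.approx(r_hand**2, abs=1e-12)
    assert out["dist_bp"].iloc[0] == 1000


def test_r2_independent_snps_near_zero():
    """Two independent SNPs at n = 1,000: mean r² over replicates < 0.02."""
    rng = np.random.default_rng(1)
    vals = []
    for _ in range(30):
        g = toy_genotypes(rng.binomial(2, 0.4, (1000, 2)).astype(float))
        vals.append(pairwise_r2(g)["r2"].iloc[0])
    assert np.mean(vals) < 0.02


def test_r2_allele_flip_invariant():
    """Swapping allele labels (x -> 2 - x) leaves r² unchanged."""
    rng = np.random.default_rng(2)
    X = rng.binomial(2, 0.35, (60, 4)).astype(float)
    a = pairwise_r2(toy_genotypes(X))
    X2 = X.copy()
    X2[:, 1] = 2 - X2[:, 1]
    b = pairwise_r2(toy_genotypes(X2))
    np.testing.assert_allclose(a["r2"].to_numpy(), b["r2"].to_numpy(), atol=1e-12)


def test_r2_monomorphic_skipped():
    X = np.column_stack([np.zeros(20), np.random.default_rng(3).integers(0, 3, 20)])
    with pytest.warns(UserWarning, match="monomorphic"):
        out = pairwise_r2(toy_genotypes(X))
    assert out.empty


def test_r2_max_distance_window():
    g = toy_genotypes(
        np.random.default_rng(4).binomial(2, 0.5, (30, 3)).astype(float),
        pos=[1000, 2000, 500_000],
    )
    out = pairwise_r2(g, max_distance_bp=10_000)
    assert set(zip(out["snp1"], out["snp2"])) == {("s0", "s1")}


def test_different_chromosomes_not_paired():
    g = toy_genotypes(
        np.random.default_rng(5).binomial(2, 0.5, (30, 2)).astype(float),
        chrom=["1", "2"],
    )
    assert pairwise_r2(g).empty


# ---------------------------------------------------------------------------
# decay


def test_decay_single_record():
    rec = pd.DataFrame(
        {"snp1": ["a"], "snp2": ["b"], "chrom": ["1"], "dist_bp": [250_000], "r2": [0.12]}
    )
    out = ld_decay(rec, 100_000)
    assert len(out) == 1
    assert out["bin_start_bp"].iloc[0] == 200_000
    assert out["mean_r2"].iloc[0] == pytest.approx(0.12)
    assert out["n_pairs"].iloc[0] == 1


def test_decay_duplicates_double_count():
    rec = pd.DataFrame(
        {"snp1": ["a", "a"], "snp2": ["b", "b"], "chrom": "1",
         "dist_bp": [50_000, 50_000], "r2": [0.3, 0.3]}
    )
    out = ld_decay(rec, 100_000)
    assert out["mean_r2"].iloc[0] == pytest.approx(0.3)
    assert out["n_pairs"].iloc[0] == 2


def test_decay_monotone_from_generator(small_genotypes):
    """Mean r² decreases with distance for gene-dropped genotypes."""
    from scipy import stats

    g = small_genotypes
    founders_only = g.subset_samples(g.samples[:120])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec = pairwise_r2(founders_only, max_distance_bp=2_000_000)
    dec = ld_decay(rec, 200_000)
    rho = stats.spearmanr(dec["bin_start_bp"], dec["mean_r2"]).statistic
    assert rho < 0
    assert "cum_mean_r2" in dec.columns


def test_decay_empty_raises():
    with pytest.raises(ValueError):
        ld_decay(pd.DataFrame(columns=["dist_bp", "r2"]), 1000)


# ---------------------------------------------------------------------------
# windows


def test_window_worked_example():
    """A SNP at chr10:18,129,602 gets the window [17,879,602; 18,379,602]."""
    snps = pd.DataFrame({"snp": ["q"], "chrom": ["10"], "pos": [18_129_602]})
    w = snp_windows(snps, half_width_bp=250_000)
    assert w["start"].iloc[0] == 17_879_602
    assert w["end"].iloc[0] == 18_379_602


def test_window_clamped_at_start():
    snps = pd.DataFrame({"snp": ["q"], "chrom": ["1"], "pos": [100_000]})
    w = snp_windows(snps, half_width_bp=250_000)
    assert w["start"].iloc[0] == 1
    assert w["end"].iloc[0] == 350_000


def test_nearby_windows_share_features():
    """Two SNPs 17,572 bp apart on one chromosome have overlapping windows
    and annotate to the same features."""
    snps = pd.DataFrame(
        {"snp": ["q1", "q2"], "chrom": ["10", "10"], "pos": [18_129_602, 18_147_174]}
    )
    w = snp_windows(snps)
    assert w["start"].iloc[1] <= w["end"].iloc[0]  # overlap
    feats = pd.DataFrame(
        {
            "feature": ["GENE_A", "GENE_B"],
            "kind": "gene",
            "chrom": "10",
            "start": [18_000_000, 18_200_000],
            "end": [18_050_000, 18_260_000],
        }
    )
    ann = annotate_windows(w, feats)
    got = ann.groupby("snp")["feature"].apply(set)
    assert got["q1"] == got["q2"] == {"GENE_A", "GENE_B"}


def test_window_translation_consistency():
    rng = np.random.default_rng(6)
    pos = rng.integers(1_000_000, 9_000_000, 10)
    snps = pd.DataFrame({"snp": [f"s{i}" for i in range(10)], "chrom": "3", "pos": pos})
    k = 12_345
    w1 = snp_windows(snps)
    w2 = snp_windows(snps.assign(pos=pos + k))
    np.testing.assert_array_equal(w2["start"].to_numpy(), w1["start"].to_numpy() + k)
    np.testing.assert_array_equal(w2["end"].to_numpy(), w1["end"].to_numpy() + k)


# ---------------------------------------------------------------------------
# annotation


def test_annotation_exact_and_boundary():
    w = pd.DataFrame({"snp": ["q"], "chrom": ["1"], "start": [100], "end": [200]})
    feats = pd.DataFrame(
        {
            "feature": ["exact", "before", "touching"],
            "kind": "gene",
            "chrom": "1",
            "start": [100, 50, 90],
            "end": [200, 99, 100],
        }
    )
    ann = annotate_windows(w, feats)
    got = dict(zip(ann["feature"], ann["overlap_bp"]))
    assert got.get("exact") == 101  # inclusive interval length
    assert "before" not in got  # ends 1 bp before the window
    assert got.get("touching") == 1


def test_annotation_toy_count():
    """5 features vs 2 windows constructed for exactly 3 intersections."""
    w = pd.DataFrame(
        {"snp": ["w1", "w2"], "chrom": ["1", "2"], "start": [100, 500], "end": [300, 700]}
    )
    feats = pd.DataFrame(
        {
            "feature": [f"f{i}" for i in range(5)],
            "kind": ["gene", "gene", "QTL", "gene", "QTL"],
            "chrom": ["1", "1", "2", "3", "2"],
            "start": [150, 400, 600, 100, 900],
            "end": [160, 450, 800, 300, 950],
        }
    )
    ann = annotate_windows(w, feats)
    assert len(ann) == 2
    assert set(ann["feature"]) == {"f0", "f2"}
    # adjust: construct a third intersection
    feats.loc[1, ["start", "end"]] = [250, 350]
    ann = annotate_windows(w, feats)
    assert len(ann) == 3
    assert set(ann["feature"]) == {"f0", "f1", "f2"}


@pytest.mark.parametrize("seed", range(5))
def test_annotation_equals_brute_force(seed):
    """Randomised instances match an all-pairs brute-force intersection."""
    rng = np.random.default_rng(seed)
    nw, nf = rng.integers(2, 20), rng.integers(10, 200)
    w = pd.DataFrame(
        {
            "snp": [f"w{i}" for i in range(nw)],
            "chrom": rng.integers(1, 4, nw).astype(str),
            "start": rng.integers(1, 10_000, nw),
        }
    )
    w["end"] = w["start"] + rng.integers(1, 5_000, nw)
    f = pd.DataFrame(
        {
            "feature": [f"f{i}" for i in range(nf)],
            "kind": "gene",
            "chrom": rng.integers(1, 4, nf).astype(str),
            "start": rng.integers(1, 10_000, nf),
        }
    )
    f["end"] = f["start"] + rng.integers(1, 3_000, nf)
    got = annotate_windows(w, f)
    expected = set()
    for wi in w.itertuples(index=False):
        for fi in f.itertuples(index=False):
            if wi.chrom == fi.chrom and max(wi.start, fi.start) <= min(wi.end, fi.end):
                expected.add((wi.snp, fi.feature))
    assert set(zip(got["snp"], got["feature"])) == expected


def test_malformed_interval_rejected():
    w = pd.DataFrame({"snp": ["q"], "chrom": ["1"], "start": [100], "end": [200]})
    feats = pd.DataFrame(
        {"feature": ["bad"], "kind": "gene", "chrom": "1", "start": [300], "end": [200]}
    )
    with pytest.raises(ValueError, match="bad"):
        annotate_windows(w, feats)


def test_chrom_label_normalisation():
    w = pd.DataFrame({"snp": ["q"], "chrom": ["chr1"], "start": [100], "end": [200]})
    feats = pd.DataFrame(
        {"feature": ["g"], "kind": "gene", "chrom": ["1"], "start": [150], "end": [180]}
    )
    assert len(annotate_windows(w, feats)) == 1


# ---------------------------------------------------------------------------
# readers


def test_read_bed_converts_coordinates(tmp_path):
    path = tmp_path / "genes.bed"
    path.write_text("track name=test\nchr1\t99\t200\tGENE_A\n1\t500\t600\tGENE_B\n")
    out = read_bed(path)
    assert out["start"].tolist() == [100, 501]  # 0-based half-open -> 1-based
    assert out["end"].tolist() == [200, 600]
    assert out["feature"].tolist() == ["GENE_A", "GENE_B"]


def test_read_bed_rejects_inverted(tmp_path):
    path = tmp_path / "bad.bed"
    path.write_text("1\t500\t500\tX\n")
    with pytest.raises(ValueError, match="empty or inverted"):
        read_bed(path)


def test_read_gff3(tmp_path):
    path = tmp_path / "ann.gff3"
    path.write_text(
        "##gff-version 3\n"
        "1\tsrc\tgene\t100\t200\t.\t+\t.\tID=g1;Name=THSD4\n"
        "1\tsrc\tQTL_region\t150\t400\t.\t.\t.\tID=q1;Name=FT12R\n"
    )
    out = read_gff3(path)
    assert out["feature"].tolist() == ["THSD4", "FT12R"]
    assert out["kind"].tolist() == ["gene", "QTL"]
    assert out["start"].tolist() == [100, 150]
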