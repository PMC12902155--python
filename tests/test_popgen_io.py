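import numpy as np
import pytest

from bgsinfer.genome_model import SelectedAnnotation, WindowedGenome
from bgsinfer.popgen_io import (
    CallableMask,
    alpha_from_fis,
    estimate_fis,
    genotype_counts_from_vcf,
    hypergeometric_projection,
    inbreeding_het_prob,
    tally_windowed_diversity,
    tally_windowed_sfs,
)


def write_vcf(path, sites, n_samples):
    """sites: list of (pos, ref, alt, genotype strings)."""
    head = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=20000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(f"s{i}" for i in range(n_samples)) + "\n"
    )
    rows = [
        f"chr1\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        for pos, ref, alt, gts in sites
    ]
    path.write_text(head + "\n".join(rows) + "\n")


@pytest.fixture
def flat_genome():
    return WindowedGenome(
        chrom=["chr1", "chr1"], start=[0, 10_000], end=[10_000, 20_000],
        L=[0.0, 0.0], callable=[10_000.0, 10_000.0], R=[1e-3, 1e-3],
        gpos=[5e-5, 1.5e-4],
    )


@pytest.fixture
def full_mask():
    return CallableMask({"chr1": np.array([[0, 20_000]])})


class TestHetProb:
    @pytest.mark.parametrize("p,F,expect", [
        (0.5, 1.0, 0.0),
        (0.5, 0.0, 0.5),
        (0.2, 0.87, 2 * 0.2 * 0.8 * 0.13),
    ])
    def test_values(self, p, F, expect):
        assert inbreeding_het_prob(p, F) == pytest.approx(expect)

    def test_domain(self):
        with pytest.raises(ValueError):
            inbreeding_het_prob(1.2, 0.0)


class TestFIS:
    def test_hwe_near_zero(self, rng):
        n = 500
        p = rng.uniform(0.1, 0.9, size=2_000)
        het = rng.binomial(n, 2 * p * (1 - p))
        hom_alt = rng.binomial(n, p**2)
        g = np.column_stack([n - het - hom_alt, het, hom_alt])
        assert abs(estimate_fis(g)) < 0.05

    def test_no_heterozygotes_near_one(self):
        g = np.array([[50, 0, 50]] * 100, dtype=float)
        assert estimate_fis(g) > 0.95

    def test_recovery_from_inbreeding_model(self, rng):
        # genotypes drawn with P(het) = 2p(1-p)(1-F)
        F, n = 0.8, 200
        rows = []
        for _ in range(10_000):
            p = rng.uniform(0.05, 0.95)
            ph = inbreeding_het_prob(p, F)
            phomd = p**2 + F * p * (1 - p)
            g = rng.multinomial(n, [1 - ph - phomd, ph, phomd])
            rows.append(g)
        fhat = estimate_fis(np.asarray(rows, dtype=float))
        assert 0.75 <= fhat <= 0.85

    def test_alpha_from_fis(self):
        assert alpha_from_fis(0.0) == 0.0
        assert alpha_from_fis(9 / 11) == pytest.approx(0.9)

    def test_monomorphic_only_raises(self):
        with pytest.raises(ValueError):
            estimate_fis(np.array([[10, 0, 0]], dtype=float))


class TestProjection:
    def test_exhaustive_enumeration_toy(self):
        # 5 sites with derived counts 1..5 of n=6, projected to 4
        from scipy.stats import hypergeom
        n, m = 6, 4
        sfs = np.zeros(n)
        sfs[1:] = 1.0
        got = hypergeometric_projection(sfs, m)
        expect = np.zeros(m)
        for j in range(1, n):
            for k in range(0, min(j, m) + 1):
                pr = hypergeom.pmf(k, n, j, m)
                if k == 0 or k >= m:
                    expect[0] += pr
                else:
                    expect[k] += pr
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_mass_conserved(self, rng):
        sfs = rng.integers(0, 50, 20).astype(float)
        got = hypergeometric_projection(sfs, 10)
        assert got.sum() == pytest.approx(sfs.sum())


class TestTallySFS:
    def test_basic_polarized_tally(self, tmp_path, flat_genome, full_mask):
        ns = 12
        vcf = tmp_path / "a.vcf"
        write_vcf(vcf, [
            (100, "A", "T", ["0/1"] * 3 + ["0/0"] * 9),        # derived j=3
            (200, "C", "G", ["1/1"] * 11 + ["0/1"]),           # anc=G: derived j=1
            (300, "A", "C", ["./."] + ["0/1"] * 11),           # missing -> removed
            (400, "A", "C", ["0/1"] * 12),                     # no outgroup -> removed
            (15_000, "G", "A", ["0/1"] * 2 + ["0/0"] * 10),    # window 1, j=2
        ], ns)
        outgroup = {("chr1", 100): "A", ("chr1", 200): "G", ("chr1", 300): "A",
                    ("chr1", 15_000): "G"}
        samples = [f"s{i}" for i in range(ns)]
        sfs, diag = tally_windowed_sfs(vcf, full_mask, flat_genome, samples,
                                       outgroup, n_target_diploids=ns)
        assert sfs.counts[0, 3] == 1 and sfs.counts[0, 1] == 1
        assert sfs.counts[0, 0] == 10_000 - 2 - 2  # two tallied, two removed
        assert sfs.counts[1, 2] == 1
        assert diag["missing_genotypes"] == 1 and diag["no_outgroup"] == 1

    def test_outgroup_polymorphic_site_noncallable(self, tmp_path, flat_genome,
                                                   full_mask):
        vcf = tmp_path / "b.vcf"
        write_vcf(vcf, [(100, "A", "T", ["0/1"] * 4)], 4)
        sfs, diag = tally_windowed_sfs(
            vcf, full_mask, flat_genome, [f"s{i}" for i in range(4)],
            {("chr1", 100): "."}, n_target_diploids=4)
        assert diag["outgroup_polymorphic"] == 1
        assert sfs.counts[0, 1:].sum() == 0
        assert sfs.counts[0, 0] == 9_999

    def test_selected_sites_excluded(self, tmp_path, flat_genome, full_mask):
        vcf = tmp_path / "c.vcf"
        write_vcf(vcf, [(100, "A", "T", ["0/1"] * 4)], 4)
        ann = SelectedAnnotation({"chr1": [[0, 1_000]]})
        sfs, diag = tally_windowed_sfs(
            vcf, full_mask, flat_genome, [f"s{i}" for i in range(4)],
            {("chr1", 100): "A"}, n_target_diploids=4, selected=ann)
        assert diag["in_selected"] == 1
        assert sfs.counts[0, 0] == 10_000 - 1_000  # CDS removed from callable

    def test_downsampling_projection_in_expectation(self, tmp_path, flat_genome,
                                                    full_mask):
        ns = 8
        vcf = tmp_path / "d.vcf"
        write_vcf(vcf, [(100, "A", "T", ["0/1"] * 6 + ["0/0"] * 2)], ns)
        samples = [f"s{i}" for i in range(ns)]
        og = {("chr1", 100): "A"}
        sfs, _ = tally_windowed_sfs(vcf, full_mask, flat_genome, samples, og,
                                    n_target_diploids=5)
        site = np.zeros(16)
        site[6] = 1.0
        expect = hypergeometric_projection(site, 10)
        np.testing.assert_allclose(sfs.counts[0, 1:], expect[1:], atol=1e-12)

    def test_missing_sample_raises(self, tmp_path, flat_genome, full_mask):
        vcf = tmp_path / "e.vcf"
        write_vcf(vcf, [(100, "A", "T", ["0/1"] * 4)], 4)
        with pytest.raises(ValueError, match="missing"):
            tally_windowed_sfs(vcf, full_mask, flat_genome, ["sX"], {},
                               n_target_diploids=1)


class TestTallyDiversity:
    def test_monomorphic_window(self, tmp_path, flat_genome, full_mask):
        vcf = tmp_path / "f.vcf"
        write_vcf(vcf, [(15_000, "A", "T", ["0/1"] * 4)], 4)
        div = tally_windowed_diversity(vcf, full_mask, flat_genome,
                                       [f"s{i}" for i in range(4)])
        assert div.p[0] == 0.0 and div.m[0] == 10_000.0

    def test_half_frequency_exact_value(self, tmp_path, flat_genome, full_mask):
        # j = n/2 with n=4: 2*2*2/(4*3) = 2/3
        vcf = tmp_path / "g.vcf"
        write_vcf(vcf, [(100, "A", "T", ["1/1", "0/0"])], 2)
        div = tally_windowed_diversity(vcf, full_mask, flat_genome, ["s0", "s1"])
        assert div.p[0] == pytest.approx(2 / 3)

    def test_matches_brute_force_pairs(self, tmp_path, flat_genome, full_mask, rng):
        ns = 6
        sites = []
        gmat = []
        for i, pos in enumerate(range(100, 2_100, 20)):
            g = rng.integers(0, 3, ns)
            gts = ["0/0", "0/1", "1/1"]
            sites.append((pos, "A", "T", [gts[x] for x in g]))
            gmat.append(g)
        vcf = tmp_path / "h.vcf"
        write_vcf(vcf, sites, ns)
        div = tally_windowed_diversity(vcf, full_mask, flat_genome,
                                       [f"s{i}" for i in range(ns)])
        # brute force: mean over all pairs of the 2n haplotypes
        total = 0.0
        n = 2 * ns
        for g in gmat:
            j = int(np.sum(g))
            total += 2 * j * (n - j) / (n * (n - 1))
        assert div.p[0] == pytest.approx(total)


class TestMask:
    def test_overlap_and_contains(self):
        m = CallableMask({"c": np.array([[0, 100], [200, 300]])})
        assert m.overlap("c", 50, 250) == 100
        assert m.contains("c", 99) and not m.contains("c", 150)
        assert m.overlap("missing", 0, 10) == 0

    def test_bed_round_trip(self, tmp_path):
        p = tmp_path / "m.bed"
        p.write_text("c\t0\t100\nc\t200\t300\n")
        m = CallableMask.from_bed(p)
        assert m.overlap("c", 0, 1_000) == 200

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError):
            CallableMask({"c": np.array([[0, 100], [50, 150]])})


def test_genotype_counts_roundtrip(tmp_path):
    vcf = tmp_path / "i.vcf"
    write_vcf(vcf, [(100, "A", "T", ["0/0", "0/1", "1/1"])], 3)
    g = genotype_counts_from_vcf(vcf)
    np.testing.assert_array_equal(g, [[1, 1, 1]])
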