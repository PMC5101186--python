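"""Interval overlap, colocalization, concordance, differential occupancy, proximity."""
import numpy as np
import pandas as pd
import pytest

from chromabench import synthetic as syn
from chromabench._errors import AnalysisError
from chromabench.io_formats import GeneAnnotation, PeakSet
from chromabench.occupancy import (
    assign_nearby_genes,
    differential_occupancy,
    overlap,
    superenhancer_colocalization,
    top_n_concordance,
    tss_peak_distance,
)


def peaks_from(records):
    return PeakSet(df=pd.DataFrame(records, columns=["chrom", "start", "end", "name"]))


def random_peaks(rng, n, max_pos=5000, max_len=200, chroms=("chr1", "chr2")):
    starts = rng.integers(0, max_pos, n)
    return peaks_from(
        [
            (rng.choice(chroms), s, s + rng.integers(1, max_len), f"p{i}")
            for i, s in enumerate(starts)
        ]
    )


def brute_force_overlap_flags(a: PeakSet, b: PeakSet, min_bp=1):
    flags = []
    for ra in a.df.itertuples(index=False):
        hit = any(
            rb.chrom == ra.chrom
            and min(ra.end, rb.end) - max(ra.start, rb.start) >= min_bp
            for rb in b.df.itertuples(index=False)
        )
        flags.append(hit)
    return np.array(flags)


class TestOverlap:
    def test_identical_sets_fraction_one(self):
        a = peaks_from([("chr1", 0, 100, "x"), ("chr1", 500, 600, "y")])
        s = overlap(a, a)
        assert s.fraction_a_overlapping == 1.0 and s.jaccard == 1.0

    def test_half_open_touching_does_not_overlap(self):
        a = peaks_from([("chr1", 0, 10, "a")])
        b = peaks_from([("chr1", 10, 20, "b")])
        assert overlap(a, b).n_a_overlapping_b == 0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            a = random_peaks(rng, 200)
            b = random_peaks(rng, 200)
            for min_bp in (1, 5, 50):
                s = overlap(a, b, min_bp=min_bp)
                fa = brute_force_overlap_flags(a, b, min_bp)
                fb = brute_force_overlap_flags(b, a, min_bp)
                assert s.n_a_overlapping_b == int(fa.sum())
                assert s.n_b_overlapping_a == int(fb.sum())

    def test_fraction_monotone_in_min_bp(self):
        rng = np.random.default_rng(23)
        a = random_peaks(rng, 150)
        b = random_peaks(rng, 150)
        fracs = [overlap(a, b, min_bp=m).fraction_a_overlapping for m in (1, 10, 50, 100)]
        assert fracs == sorted(fracs, reverse=True)

    def test_jaccard_symmetric(self):
        rng = np.random.default_rng(29)
        a = random_peaks(rng, 80)
        b = random_peaks(rng, 80)
        assert overlap(a, b).jaccard == overlap(b, a).jaccard

    def test_unknown_chromosome_warns_and_counts_zero(self):
        a = peaks_from([("chrX", 0, 10, "a")])
        b = peaks_from([("chr1", 0, 10, "b")])
        with pytest.warns(UserWarning, match="only one set"):
            assert overlap(a, b).n_a_overlapping_b == 0


class TestColocalization:
    def test_88_of_142_superenhancers_is_62_percent(self):
        ses = peaks_from([("chr1", i * 10000, i * 10000 + 5000, f"se{i}") for i in range(142)])
        peaks = peaks_from(
            [("chr1", i * 10000 + 100, i * 10000 + 600, f"p{i}") for i in range(88)]
        )
        enhancers = peaks_from([("chr2", 0, 100, "e0")])
        s = superenhancer_colocalization(peaks, enhancers, ses)
        assert (s.n_se_cobound, s.se_fraction_percent) == (88, 62)

    def test_full_coverage_is_100_percent(self):
        ses = peaks_from([("chr1", i * 1000, i * 1000 + 500, f"se{i}") for i in range(10)])
        s = superenhancer_colocalization(ses, ses, ses)
        assert s.se_fraction_percent == 100

    def test_empty_superenhancer_set_not_applicable(self):
        a = peaks_from([("chr1", 0, 10, "a")])
        empty = PeakSet(df=pd.DataFrame(columns=["chrom", "start", "end", "name"]))
        assert superenhancer_colocalization(a, a, empty).se_fraction_percent is None

    def test_planted_fraction_recovered_exactly(self):
        genome = {f"chr{i}": 2_000_000 for i in range(1, 5)}
        peaks, enh, ses, truth = syn.simulate_peaks(genome, 500, 500, 0.6,
                                                    n_superenhancers=100, seed=31)
        s = superenhancer_colocalization(peaks, enh, ses)
        assert s.n_se_cobound == truth.peak_counts["n_se_overlapping_a"] == 60


class TestConcordance:
    def build(self, enr_b):
        n = len(enr_b)
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n) * 1000,
                "end": np.arange(n) * 1000 + 500,
                "name": [f"p{i}" for i in range(n)],
                "enrichment_A": np.linspace(50, 1, n),
                "enrichment_B": enr_b,
            }
        )
        return PeakSet(df=df)

    def test_all_concordant(self):
        s = top_n_concordance(self.build([10.0] * 30), n=20)
        assert s.n_discordant == 0

    def test_all_discordant(self):
        s = top_n_concordance(self.build([1.0] * 30), n=20)
        assert s.n_discordant == 20

    def test_threshold_is_strict(self):
        s = top_n_concordance(self.build([2.0] * 10), n=10, fold_threshold=2.0)
        assert s.n_discordant == 0  # 2.0 < 2.0 is false

    def test_planted_discordance_exact(self):
        peaks = syn.tiled_peaks(12000, seed=1)
        two, truth = syn.plant_two_method_enrichments(peaks, 10000, 33, seed=2)
        s = top_n_concordance(two, n=10000)
        assert s.n_discordant == truth.peak_counts["n_discordant"] == 33

    def test_n_truncated_with_warning(self):
        with pytest.warns(UserWarning, match="truncating"):
            s = top_n_concordance(self.build([1.0] * 5), n=10)
        assert s.n == 5

    def test_missing_column_is_input_error(self):
        peaks = peaks_from([("chr1", 0, 10, "a")])
        with pytest.raises(AnalysisError, match="enrichment"):
            top_n_concordance(peaks)


class TestDifferentialOccupancy:
    def test_identical_conditions_no_calls(self):
        rng = np.random.default_rng(3)
        base = rng.integers(50, 500, 100)
        counts = pd.DataFrame(
            {f"{c}_r{r}": base for c in ("2iL", "serum") for r in (1, 2, 3)},
            index=[f"R{i}" for i in range(100)],
        )
        design = {f"{c}_r{r}": (c, r) for c in ("2iL", "serum") for r in (1, 2, 3)}
        res = differential_occupancy(counts, design, "2iL", "serum")
        assert not res.preferential("2iL") and not res.preferential("serum")

    def test_single_region_bh_identity(self):
        counts = pd.DataFrame(
            {"a_r1": [100], "a_r2": [140], "b_r1": [90], "b_r2": [120]}, index=["R0"]
        )
        design = {"a_r1": ("A", 1), "a_r2": ("A", 2), "b_r1": ("B", 1), "b_r2": ("B", 2)}
        res = differential_occupancy(counts, design, "A", "B")
        row = res.table.iloc[0]
        assert row["p_adj"] == row["p"]

    def test_preference_flags_mutually_exclusive(self):
        counts, design, _ = syn.simulate_region_counts(300, 30, seed=19)
        res = differential_occupancy(counts, design, "2iL", "serum", moderate_variance=True)
        both = res.preferential("2iL") & res.preferential("serum")
        assert both == set()

    def test_planted_preferential_recovered(self):
        counts, design, truth = syn.simulate_region_counts(
            1000, 50, fold=4.0, dispersion=0.05, n_replicates=3, seed=20170915
        )
        res = differential_occupancy(counts, design, "2iL", "serum", moderate_variance=True)
        planted = {r for r, e in truth.differential_effects.items() if e != 0}
        pref = res.preferential("2iL")
        assert len(pref & planted) >= 45
        assert len((pref | res.preferential("serum")) - planted) <= 2

    def test_null_calls_rare_across_seeds(self):
        # planted-null FDR sanity: <= 1% of regions called preferential overall
        total_called = 0
        total_regions = 0
        for seed in range(50):
            counts, design, _ = syn.simulate_region_counts(
                200, 0, dispersion=0.05, seed=900 + seed
            )
            res = differential_occupancy(counts, design, "2iL", "serum",
                                         moderate_variance=True)
            total_called += len(res.preferential("2iL")) + len(res.preferential("serum"))
            total_regions += 200
        assert total_called / total_regions <= 0.01


class TestGeneProximity:
    def test_distance_convention(self):
        # TSS at 5,000 with peak [0, 1000): last covered base 999 -> 4,001
        assert tss_peak_distance(5000, 0, 1000) == 4001
        assert tss_peak_distance(500, 0, 1000) == 0  # inside
        assert tss_peak_distance(20000, 0, 1000) == 19001

    def test_strictly_below_threshold(self):
        peaks = peaks_from([("chr1", 0, 1000, "p0")])
        genes = GeneAnnotation(
            df=pd.DataFrame(
                {"gene_id": ["near", "far", "border"], "chrom": "chr1",
                 "tss": [5000, 20000, 10999], "strand": ["+", "-", "+"]}
            )
        )
        prox = assign_nearby_genes(peaks, genes, max_distance=10000)
        # border gene sits exactly at distance 10,000: excluded by the strict rule
        assert prox.genes_near == {"near"}

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            peaks = random_peaks(rng, 60, max_pos=100_000, max_len=2000)
            genes = GeneAnnotation(
                df=pd.DataFrame(
                    {
                        "gene_id": [f"G{i}" for i in range(80)],
                        "chrom": rng.choice(["chr1", "chr2"], 80),
                        "tss": rng.integers(0, 110_000, 80),
                        "strand": rng.choice(["+", "-"], 80),
                    }
                )
            )
            prox = assign_nearby_genes(peaks, genes, max_distance=5000)
            expected = set()
            for g in genes.df.itertuples(index=False):
                for p in peaks.df.itertuples(index=False):
                    if p.chrom == g.chrom and tss_peak_distance(g.tss, p.start, p.end) < 5000:
                        expected.add((p.name, g.gene_id))
            got = set(zip(prox.pairs["peak_name"], prox.pairs["gene_id"]))
            assert got == expected

    def test_forward_and_inverse_maps_agree(self):
        rng = np.random.default_rng(43)
        peaks = random_peaks(rng, 40, max_pos=50_000, max_len=1000)
        genes = GeneAnnotation(
            df=pd.DataFrame(
                {"gene_id": [f"G{i}" for i in range(40)], "chrom": "chr1",
                 "tss": rng.integers(0, 60_000, 40), "strand": "+"}
            )
        )
        prox = assign_nearby_genes(peaks, genes)
        forward = {(p, g) for p, gs in prox.peak_to_genes.items() for g in gs}
        inverse = {(p, g) for g, ps in prox.gene_to_peaks.items() for p in ps}
        assert forward == inverse
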