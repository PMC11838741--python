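"""Synthetic cohort generator: determinism, composition, generative truth."""

import numpy as np
import pytest
from scipy import stats

from cmmosaic.sbs import CHANNELS_96, standardize_context
from cmmosaic.synth import (
    CapacityError,
    CohortDesign,
    PlacementError,
    default_phaseable_intervals,
    generate_cohort,
    generate_gene_models,
    generate_reference,
    simulate_burdens,
    simulate_counts_matrix,
)


class TestReference:
    def test_deterministic_under_fixed_seed(self):
        a = generate_reference(1000, 0.5, seed=1)
        b = generate_reference(1000, 0.5, seed=1)
        assert a.sequence == b.sequence

    def test_gc_zero_gives_at_only(self):
        ref = generate_reference(100_000, gc_fraction=0.0, seed=2)
        assert set(ref.sequence) <= {"A", "T"}

    def test_gc_fraction_within_binomial_bound(self):
        # SD of GC proportion at n=1e6 is ~0.0005; +-0.01 is 20 SDs
        ref = generate_reference(1_000_000, gc_fraction=0.41, seed=3)
        gc = sum(ref.sequence.count(b) for b in "GC") / ref.length
        assert gc == pytest.approx(0.41, abs=0.01)

    def test_short_reference_rejected(self):
        with pytest.raises(ValueError):
            generate_reference(100, 0.5, seed=1)

    def test_fasta_roundtrip(self, toy_ref, tmp_path):
        import pyfaidx

        path = tmp_path / "ref.fa"
        toy_ref.to_fasta(str(path))
        fa = pyfaidx.Fasta(str(path))
        assert str(fa["chrS"][:]) == toy_ref.sequence


class TestGeneModels:
    def test_nonoverlap_and_cds_frame(self, toy_ref):
        gm = generate_gene_models(toy_ref, 10, seed=1, gene_length=6000, flank=1500)
        assert len(gm) == 10
        spans = sorted((g.start, g.end) for g in gm)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2
        for g in gm:
            assert g.cds_length() % 3 == 0
            assert len(g.exons) >= 1

    def test_empty_set(self, toy_ref):
        from cmmosaic.annotation import annotate_region
        from cmmosaic.sbs import VariantCall

        gm = generate_gene_models(toy_ref, 0, seed=1)
        assert len(gm) == 0
        assert annotate_region(VariantCall("chrS", 5000, "A", "C"), gm) == "intergenic"

    def test_both_strands_across_seed_sweep(self, toy_ref):
        for seed in range(20):
            gm = generate_gene_models(toy_ref, 10, seed=seed, gene_length=6000, flank=1500)
            strands = {g.strand for g in gm}
            assert strands == {"+", "-"}

    def test_capacity_error(self, toy_ref):
        with pytest.raises(CapacityError):
            generate_gene_models(toy_ref, 100, seed=1, gene_length=9000)

    def test_gff3_roundtrip(self, toy_genes, tmp_path):
        from cmmosaic.genes import GeneModelSet

        path = tmp_path / "genes.gff3"
        toy_genes.to_gff3(str(path))
        back = GeneModelSet.from_gff3(str(path))
        assert len(back) == len(toy_genes)
        for a, b in zip(toy_genes, back):
            assert (a.gene_id, a.strand, a.start, a.end) == (b.gene_id, b.strand, b.start, b.end)
            assert a.exons == b.exons
            assert (a.cds_start, a.cds_end) == (b.cds_start, b.cds_end)


class TestBurdenTruth:
    def test_noiseless_control_burden_exact(self):
        d = CohortDesign(n_control_donors=4, cells_per_donor=3, beta0=100, beta1=0,
                         sigma_u=0, sigma_e=0, seed=1)
        tab = simulate_burdens(d)
        assert (tab["burden_per_gb"] == 100.0).all()

    def test_ihd_excess_exact_in_noiseless_case(self):
        """The disease offset reproduces exactly with all noise off."""
        d = CohortDesign(n_control_donors=3, n_ihd_donors=3, cells_per_donor=2,
                         ages=[10, 40, 70, 10, 40, 70], beta0=100, beta1=2,
                         beta_I=686.0, sigma_u=0, sigma_e=0, seed=1)
        tab = simulate_burdens(d)
        ctrl = tab[tab.condition == "control"].groupby("age")["burden_per_gb"].mean()
        ihd = tab[tab.condition == "IHD"].groupby("age")["burden_per_gb"].mean()
        np.testing.assert_allclose(ihd - ctrl, 686.0)

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            CohortDesign(sigma_u=-1)
        with pytest.raises(ValueError):
            CohortDesign(signature_exposure_by_condition={"control": {"S1": 0.7}})
        with pytest.raises(ValueError):
            CohortDesign(n_control_donors=2, ages=[10.0])


class TestCohortGeneration:
    def make(self, seed=5, **kw):
        ref = generate_reference(150_000, 0.41, seed=seed)
        design = CohortDesign(
            n_control_donors=3, n_ihd_donors=2, cells_per_donor=2,
            beta0=1.0e7, beta1=0.0, beta_I=2.0e6, sigma_u=0, sigma_e=0, seed=seed,
            **kw,
        )
        return ref, design

    def test_fixture_bundle_deterministic(self, catalog4, tmp_path):
        ref, design = self.make()
        bundles = []
        for name in ("a", "b"):
            truth = generate_cohort(design, ref, catalog4)
            paths = truth.write(str(tmp_path / name))
            bundles.append(paths)
        import hashlib

        for key in bundles[0]:
            h = [hashlib.sha256(open(b[key], "rb").read()).hexdigest() for b in bundles]
            assert h[0] == h[1], f"fixture {key} not byte-identical"

    def test_vcf_roundtrip_through_pysam(self, catalog4, tmp_path):
        """Written per-cell VCFs read back identically via the pysam reader."""
        from cmmosaic.fileio import read_vcf

        ref, design = self.make(seed=12)
        truth = generate_cohort(design, ref, catalog4)
        paths = truth.write(str(tmp_path / "bundle"))
        cell = truth.cells["cell_id"].iloc[0]
        back = read_vcf(paths[f"vcf:{cell}"], cell_id=cell)
        orig = sorted(truth.mutations[cell], key=lambda c: c.pos)
        assert [(c.pos, c.ref, c.alt) for c in back] == [
            (c.pos, c.ref, c.alt) for c in orig
        ]
        assert all(c.phaseable for c in back)

    def test_vcf_ref_matches_fasta(self, catalog4):
        ref, design = self.make(seed=6)
        truth = generate_cohort(design, ref, catalog4)
        for calls in truth.mutations.values():
            for c in calls:
                assert ref.sequence[c.pos - 1].upper() == c.ref

    def test_mutations_inside_phaseable_intervals(self, catalog4):
        ref, design = self.make(seed=7)
        truth = generate_cohort(design, ref, catalog4)
        for calls in truth.mutations.values():
            for c in calls:
                assert any(s < c.pos <= e for _, s, e in truth.phaseable)

    def test_no_duplicate_sites_within_cell(self, catalog4):
        ref, design = self.make(seed=8)
        truth = generate_cohort(design, ref, catalog4)
        for calls in truth.mutations.values():
            pos = [c.pos for c in calls]
            assert len(pos) == len(set(pos))

    def test_realized_counts_within_poisson_bound(self, catalog4):
        ref, design = self.make(seed=9)
        truth = generate_cohort(design, ref, catalog4)
        total = truth.cells["realized_mutations"].sum()
        expect = truth.cells["expected_mutations"].sum()
        assert abs(total - expect) <= 4 * np.sqrt(expect)

    def test_single_signature_spectrum_matches_column(self, catalog4):
        """Pooled spectrum of a one-signature cohort matches that column."""
        from cmmosaic.sbs import build_spectrum

        ref, design = self.make(
            seed=10,
            signature_exposure_by_condition={
                "control": {"S1": 1.0},
                "IHD": {"S1": 1.0},
            },
        )
        truth = generate_cohort(design, ref, catalog4)
        calls = [c for v in truth.mutations.values() for c in v]
        assert len(calls) >= 5000
        spec = build_spectrum(calls, {"chrS": ref.sequence})
        col = catalog4.column("S1")
        cos = spec.counts @ col / (np.linalg.norm(spec.counts) * np.linalg.norm(col))
        assert cos >= 0.98

    def test_context_histogram_chisquare_gof(self, catalog4):
        """Pooled channel histogram is consistent with the catalog mixture."""
        from cmmosaic.sbs import build_spectrum

        ref, design = self.make(seed=11)
        truth = generate_cohort(design, ref, catalog4)
        calls = [c for v in truth.mutations.values() for c in v]
        assert len(calls) >= 10_000
        spec = build_spectrum(calls, {"chrS": ref.sequence})
        expected = catalog4.matrix.mean(axis=1) * spec.total
        keep = expected >= 5
        chi2 = ((spec.counts[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.001

    def test_placement_error_names_context(self, catalog4, rng):
        from cmmosaic.synth import place_mutations

        tiny_idx = {t: np.array([], dtype=np.int64) for t in ["ACA"]}
        counts = np.zeros(96, dtype=int)
        counts[CHANNELS_96.index("A[C>A]A")] = 3
        with pytest.raises(PlacementError, match="ACA"):
            place_mutations(counts, tiny_idx, "ACACACA", "c", rng)


class TestCountsMatrix:
    def test_null_design_lfc_centred_at_zero(self):
        counts, meta, genes = simulate_counts_matrix(
            n_donors_per_condition=3, cells_per_donor=80, n_genes=100, seed=1
        )
        ihd = (meta["condition"] == "IHD").to_numpy()
        lib = counts.sum(axis=1, keepdims=True).astype(float)
        norm = counts / lib * 1e4
        lfc = np.log(norm[ihd].mean(axis=0) + 1) - np.log(norm[~ihd].mean(axis=0) + 1)
        assert abs(np.median(lfc)) < 0.05

    def test_condition_shift_visible_in_every_donor_subset(self):
        counts, meta, genes = simulate_counts_matrix(
            n_donors_per_condition=3, cells_per_donor=80, n_genes=50,
            de_genes=[{"gene": 0, "lfc": 2.0, "condition": "IHD"}], seed=2,
        )
        for drop_c in [f"CTRL-{i}" for i in (1, 2, 3)]:
            for drop_i in [f"IHD-{i}" for i in (1, 2, 3)]:
                mask = ~meta["donor_id"].isin([drop_c, drop_i]).to_numpy()
                sub, msub = counts[mask], meta[mask]
                ihd = (msub["condition"] == "IHD").to_numpy()
                lib = sub.sum(axis=1, keepdims=True).astype(float)
                norm = sub / lib * 1e4
                lfc = np.log(norm[ihd, 0].mean() + 1) - np.log(norm[~ihd, 0].mean() + 1)
                assert lfc > 1.0

    def test_single_donor_artifact_vanishes_without_that_donor(self):
        counts, meta, genes = simulate_counts_matrix(
            n_donors_per_condition=3, cells_per_donor=80, n_genes=50,
            de_genes=[{"gene": 5, "lfc": 3.0, "donor": "IHD-1"}], seed=3,
        )
        mask = (meta["donor_id"] != "IHD-1").to_numpy()
        sub, msub = counts[mask], meta[mask]
        ihd = (msub["condition"] == "IHD").to_numpy()
        lib = sub.sum(axis=1, keepdims=True).astype(float)
        norm = sub / lib * 1e4
        lfc = np.log(norm[ihd, 5].mean() + 1) - np.log(norm[~ihd, 5].mean() + 1)
        assert abs(lfc) < 0.25

    def test_unknown_gene_index_rejected(self):
        with pytest.raises(ValueError):
            simulate_counts_matrix(n_genes=10, de_genes=[{"gene": 10, "lfc": 1.0}])

    def test_single_donor_per_condition_rejected(self):
        with pytest.raises(ValueError):
            simulate_counts_matrix(n_donors_per_condition=1)
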