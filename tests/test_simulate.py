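"""The planted-truth generator: determinism, round trips, separation."""

import numpy as np
import pandas as pd
import pytest

from embryoarray.io import read_gmt, write_gmt
from embryoarray.motifs import scan_sequence
from embryoarray.simulate import (
    AnnotationConfig,
    PlantedTruth,
    StudyDesign,
    TruthConfig,
    generate_annotations,
    generate_probe_intensities,
    plant_gene_means,
    well_separated_profiles,
)


class TestStudyDesign:
    def test_default_is_sixteen_arrays(self):
        d = StudyDesign()
        assert d.n_samples == 16
        assert len(d.cells()) == 8

    def test_bad_dimensions_name_the_field(self):
        with pytest.raises(ValueError, match="n_genes"):
            StudyDesign(n_genes=0)
        with pytest.raises(ValueError, match="replicates_per_cell"):
            StudyDesign(replicates_per_cell=1)
        with pytest.raises(ValueError, match="n_probes_per_set"):
            StudyDesign(n_probes_per_set=0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise SD"):
            TruthConfig(probe_noise_sd=-0.1)

    def test_small_de_effect_rejected(self):
        with pytest.raises(ValueError, match="de_effect"):
            TruthConfig(de_effect=0.5)


SMALL = dict(n_patterns=2, genes_per_pattern=5,
             genotype_symmetric_patterns=True, n_de_up_per_stage=1,
             n_de_down_per_stage=1, n_absent_genes=3)


class TestGenerateProbeIntensities:
    def test_seed_determinism_byte_identical(self):
        design = StudyDesign(n_genes=30, n_probes_per_set=5, seed=1)
        a = generate_probe_intensities(design, TruthConfig(**SMALL))
        b = generate_probe_intensities(design, TruthConfig(**SMALL))
        pd.testing.assert_frame_equal(a.probes.data, b.probes.data)
        assert a.probes.data.to_csv() == b.probes.data.to_csv()

    def test_different_seed_differs(self):
        cfg = TruthConfig(**SMALL)
        a = generate_probe_intensities(StudyDesign(n_genes=30, seed=1), cfg)
        b = generate_probe_intensities(StudyDesign(n_genes=30, seed=2), cfg)
        assert not a.probes.data["PM"].equals(b.probes.data["PM"])

    def test_noiseless_roundtrip_through_median_polish(self):
        from embryoarray.preprocess import median_polish_summarize
        design = StudyDesign(n_genes=8, n_probes_per_set=11, seed=2)
        cfg = TruthConfig(n_patterns=0, n_de_up_per_stage=0,
                          n_de_down_per_stage=0, n_absent_genes=0,
                          probe_noise_sd=0.0, replicate_sd=0.0,
                          baseline_range=(8.0, 8.0))
        ds = generate_probe_intensities(design, cfg)
        for gene in design.gene_ids()[:3]:
            out = median_polish_summarize(ds.probes.pm_matrix(gene))
            assert np.allclose(out, 8.0, atol=1e-6)

    def test_mm_tracks_pm_for_absent_genes(self):
        design = StudyDesign(n_genes=30, seed=3)
        cfg = TruthConfig(**{**SMALL, "probe_noise_sd": 0.0,
                             "replicate_sd": 0.0})
        ds = generate_probe_intensities(design, cfg)
        absent = ds.truth.absent_genes[0]
        block = ds.probes.data[ds.probes.data["probe_set_id"] == absent]
        assert np.allclose(block["PM"], block["MM"])

    def test_roles_exceeding_genes_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            generate_probe_intensities(StudyDesign(n_genes=5),
                                       TruthConfig(**SMALL))

    def test_planted_de_effects_at_least_one_log2(self):
        design = StudyDesign(n_genes=40, seed=4)
        ds = generate_probe_intensities(design, TruthConfig(**SMALL))
        for stage, shifts in ds.truth.de_genes.items():
            assert all(abs(e) >= 1.0 for e in shifts.values())

    def test_truth_round_trips_through_json(self, tmp_path):
        import json
        design = StudyDesign(n_genes=40, seed=4)
        ds = generate_probe_intensities(design, TruthConfig(**SMALL))
        path = tmp_path / "truth.json"
        path.write_text(json.dumps(ds.truth.to_dict()))
        back = PlantedTruth.from_dict(json.loads(path.read_text()))
        assert back.pattern_assignments == ds.truth.pattern_assignments
        assert back.de_genes == ds.truth.de_genes


class TestPrototypes:
    def test_separation_bound_enforced(self):
        protos = well_separated_profiles(13, 8, max_r=0.5, seed=0)
        corr = np.corrcoef(protos)
        np.fill_diagonal(corr, -1.0)
        assert corr.max() < 0.5

    def test_rows_standardized(self):
        protos = well_separated_profiles(5, 6, seed=1)
        assert np.allclose(protos.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(protos.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_infeasible_request_rejected(self):
        with pytest.raises(ValueError, match="could not place"):
            well_separated_profiles(40, 3, max_r=0.3, seed=0)

    def test_planted_means_respect_prototypes(self):
        design = StudyDesign(n_genes=40, seed=5)
        cfg = TruthConfig(**SMALL)
        rng = np.random.default_rng(design.seed)
        means, truth = plant_gene_means(design, cfg, rng)
        for gene, pid in truth.pattern_assignments.items():
            profile = means.loc[gene].to_numpy()
            proto = np.asarray(truth.pattern_prototypes[pid])
            r = np.corrcoef(profile, proto)[0, 1]
            assert r > 0.999


class TestAnnotations:
    def _dataset(self, seed=6):
        design = StudyDesign(n_genes=60, seed=seed)
        cfg = TruthConfig(n_patterns=2, genes_per_pattern=10,
                          genotype_symmetric_patterns=True,
                          n_de_up_per_stage=1, n_de_down_per_stage=1,
                          n_absent_genes=3)
        return generate_probe_intensities(design, cfg)

    def test_gmt_line_count_equals_planted_terms(self, tmp_path):
        ds = self._dataset()
        ann = generate_annotations(ds, AnnotationConfig(
            promoter_length=120, n_background_terms=4))
        path = tmp_path / "t.gmt"
        write_gmt(ann["gmt"], path)
        n_lines = len(path.read_text().strip().split("\n"))
        assert n_lines == len(ann["gmt"]) == 2 + 4

    def test_gmt_round_trip(self, tmp_path):
        ds = self._dataset()
        ann = generate_annotations(ds, AnnotationConfig(promoter_length=120))
        path = tmp_path / "t.gmt"
        write_gmt(ann["gmt"], path)
        assert read_gmt(path) == ann["gmt"]

    def test_planted_motif_sites_are_exact_matches(self):
        ds = self._dataset()
        ann = generate_annotations(ds, AnnotationConfig(promoter_length=200))
        for motif_id, carriers in ds.truth.planted_motifs.items():
            consensus = ann["motifs"][motif_id]
            for gene in carriers:
                assert scan_sequence(ann["promoters"][gene], consensus) >= 1

    def test_background_promoters_motif_free(self):
        ds = self._dataset()
        ann = generate_annotations(ds, AnnotationConfig(promoter_length=200))
        carriers = {g for gl in ds.truth.planted_motifs.values() for g in gl}
        free = [g for g in ds.design.gene_ids() if g not in carriers][:20]
        for gene in free:
            for consensus in ann["motifs"].values():
                assert scan_sequence(ann["promoters"][gene], consensus) == 0

    def test_tf_genes_belong_to_their_motifs_pattern(self):
        ds = self._dataset()
        generate_annotations(ds, AnnotationConfig(promoter_length=200))
        for tf, motif_id in ds.truth.tf_map.items():
            assert tf in ds.truth.pattern_assignments

    def test_motif_shorter_than_promoter_enforced(self):
        with pytest.raises(ValueError, match="shorter than"):
            AnnotationConfig(promoter_length=5)

    def test_non_iupac_motif_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            AnnotationConfig(motifs={"bad": "AXGT"})
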