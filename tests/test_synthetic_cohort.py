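import io

import numpy as np
import pandas as pd
import pytest

from mtcn import qpcr_quant
from mtcn.synthetic_cohort import (
    CohortConfig,
    CohortConfigError,
    MT_LENGTH,
    simulate_cohort,
    simulate_depth_profiles,
    simulate_mtdna_genotypes,
    simulate_phenotypes,
    simulate_qpcr_plates,
    write_participants_csv,
    write_plates_csv,
)
from mtcn.mito_popgen import private_variants
from mtcn.cohort_assoc import score_pclc


class TestConfigValidation:
    def test_negative_count_rejected(self):
        with pytest.raises(CohortConfigError):
            CohortConfig(group_sizes={"G1/HS": -1})

    def test_bad_cell_key_rejected(self):
        with pytest.raises(CohortConfigError):
            CohortConfig(group_sizes={"G4/HS": 5})

    def test_shares_must_sum_below_one(self):
        with pytest.raises(CohortConfigError):
            CohortConfig(variance_shares=(0.5, 0.4, 0.2))

    def test_h_outside_unit_interval_rejected(self):
        with pytest.raises(CohortConfigError):
            CohortConfig(maternal_h=1.5)

    def test_prevalence_outside_unit_interval_rejected(self):
        with pytest.raises(CohortConfigError):
            CohortConfig(ptsd_prevalence={"G1/HS": 1.2})

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(CohortConfigError):
            CohortConfig(nuclear_depth=0.0)

    def test_unknown_key_rejected(self):
        with pytest.raises(CohortConfigError, match="unknown config keys"):
            CohortConfig.from_dict({"n_platez": 17})


class TestSimulateCohort:
    def test_default_counts_match_cohort(self):
        parts, latents = simulate_cohort(CohortConfig(seed=0))
        assert len(parts) == 196
        counts = parts.groupby(["generation", "group"]).size()
        assert counts[("G1", "HS")] == 15
        assert counts[("G2", "HS")] == 60
        assert counts[("G3", "HS")] == 42
        assert counts[("G1", "CTRL")] == 22
        assert counts[("G2", "CTRL")] == 37
        assert counts[("G3", "CTRL")] == 20
        assert len(latents) == 196

    def test_determinism_byte_identical(self, small_config):
        out = []
        for _ in range(2):
            parts, _ = simulate_cohort(small_config)
            buf = io.StringIO()
            write_participants_csv(parts, buf)
            out.append(buf.getvalue())
        assert out[0] == out[1]

    def test_different_seeds_differ(self, small_config):
        a, _ = simulate_cohort(small_config)
        cfg2 = CohortConfig.from_dict(
            {**{f: getattr(small_config, f) for f in
                ("group_sizes", "n_plates", "n_batches")}, "seed": 99})
        b, _ = simulate_cohort(cfg2)
        assert not a["age"].equals(b["age"])

    def test_ids_unique_ages_positive(self, default_config):
        parts, _ = simulate_cohort(default_config)
        assert parts["id"].is_unique
        assert (parts["age"] > 0).all()

    def test_pedigree_consistency(self, default_config):
        parts, _ = simulate_cohort(default_config)
        meta = parts.set_index("id")
        gen_index = {"G1": 0, "G2": 1, "G3": 2}
        for _, row in parts.iterrows():
            for col in ("mother_id", "father_id"):
                pid = row[col]
                if pid is None:
                    continue
                parent = meta.loc[pid]
                assert gen_index[parent["generation"]] == \
                    gen_index[row["generation"]] - 1
                if col == "mother_id":
                    assert parent["sex"] == "F"
                else:
                    assert parent["sex"] == "M"

    def test_maternal_lineage_recomputed_by_traversal(self, default_config):
        parts, _ = simulate_cohort(default_config)
        meta = parts.set_index("id")

        def recompute(pid):
            row = meta.loc[pid]
            if row["generation"] == "G1":
                return row["group"] == "HS"
            if row["mother_id"] is None:
                return False
            return recompute(row["mother_id"])

        for pid, stored in zip(parts["id"], parts["maternal_hs_lineage"]):
            assert recompute(pid) == stored

    def test_null_effects_give_similar_group_means(self):
        cfg = CohortConfig(group_beta=0.0, age_slope=0.0, sex_beta=0.0,
                           maternal_h=0.0, seed=21)
        parts, latents = simulate_cohort(cfg)
        merged = parts.merge(latents, on="id")
        merged["log_cn"] = np.log(merged["true_cn"])
        hs = merged.loc[merged["group"] == "HS", "log_cn"]
        ctrl = merged.loc[merged["group"] == "CTRL", "log_cn"]
        se = np.sqrt(hs.var() / len(hs) + ctrl.var() / len(ctrl))
        assert abs(hs.mean() - ctrl.mean()) < 3 * se

    def test_perfect_transmission_limit(self):
        cfg = CohortConfig(maternal_h=1.0, cn_noise_sd=0.0, group_beta=0.4,
                           linked_fraction=0.6, seed=22)
        parts, latents = simulate_cohort(cfg)
        cn = latents.set_index("id")["true_cn"]
        meta = parts.set_index("id")
        # fixed effects are group_beta * lineage only; deviation = log cn - fixed
        def dev(pid):
            fx = 0.4 * float(meta.loc[pid, "maternal_hs_lineage"])
            return np.log(cn[pid]) - fx

        checked = 0
        for _, row in parts.iterrows():
            if row["mother_id"] is None or row["generation"] == "G1":
                continue
            assert dev(row["id"]) == pytest.approx(dev(row["mother_id"]), abs=1e-12)
            checked += 1
        assert checked > 10

    def test_impossible_pedigree_errors(self):
        cfg_kwargs = dict(
            group_sizes={"G1/HS": 2, "G2/HS": 60},
            linked_fraction=1.0, max_children_per_mother=2, seed=1)
        with pytest.raises(CohortConfigError, match="exceed mother capacity"):
            simulate_cohort(CohortConfig(**cfg_kwargs))

    def test_dropout_reduces_cohort(self):
        cfg = CohortConfig(dropout_rate=0.17, seed=5)
        parts, latents = simulate_cohort(cfg)
        assert len(parts) < 196
        assert len(parts) == len(latents)


class TestSimulateQpcrPlates:
    def test_default_layout_17_plates_3_batches(self, default_config):
        parts, latents = simulate_cohort(default_config)
        wells = simulate_qpcr_plates(parts, latents, default_config)
        assert wells["plate_id"].nunique() == 17
        assert wells["batch_id"].nunique() == 3
        for (_, gene), run in wells.groupby(["plate_id", "gene"]):
            assert (run["role"] == "REF").sum() == 3
            assert (run["role"] == "NTC").sum() >= 1
        per_sample = wells[wells["role"] == "SAMPLE"].groupby(
            ["sample_id", "gene"]).size()
        assert (per_sample == 2).all()

    def test_noiseless_duplicates_identical(self, small_config):
        cfg = CohortConfig.from_dict({
            "group_sizes": small_config.group_sizes, "n_plates": 3,
            "n_batches": 2, "blood_subset_size": 5,
            "variance_shares": (0.0, 0.0, 0.0), "well_noise_sd": 0.0,
            "ntc_contamination_rate": 0.0, "amplification_failure_rate": 0.0,
            "seed": 3})
        parts, latents = simulate_cohort(cfg)
        wells = simulate_qpcr_plates(parts, latents, cfg)
        spread = wells[wells["role"] == "SAMPLE"].groupby(
            ["sample_id", "gene"])["ct"].agg(lambda s: s.max() - s.min())
        assert (spread == 0).all()

    def test_fourfold_template_two_cycles_below_ref(self):
        cfg = CohortConfig(
            group_sizes={"G1/HS": 1}, n_plates=1, n_batches=1,
            variance_shares=(0.0, 0.0, 0.0), well_noise_sd=0.0,
            plate_shift_sd=0.5, cn_noise_sd=0.0,
            ntc_contamination_rate=0.0, amplification_failure_rate=0.0,
            blood_subset_size=1, linked_fraction=0.0, seed=4)
        parts, latents = simulate_cohort(cfg)
        latents["true_cn"] = 4.0  # force 4x the reference template
        wells = simulate_qpcr_plates(parts, latents, cfg)
        cyb = wells[wells["gene"] == "MT_CYB"]
        ref_ct = cyb.loc[cyb["role"] == "REF", "ct"].mean()
        sample_ct = cyb.loc[cyb["role"] == "SAMPLE", "ct"].iloc[0]
        assert sample_ct == pytest.approx(ref_ct - 2.0, abs=1e-12)

    def test_capacity_exceeded_errors(self):
        cfg = CohortConfig(group_sizes={"G2/HS": 60}, n_plates=2,
                           n_batches=1, wells_per_plate=96,
                           linked_fraction=0.0, blood_subset_size=5, seed=5)
        parts, latents = simulate_cohort(cfg)
        with pytest.raises(CohortConfigError, match="capacity"):
            simulate_qpcr_plates(parts, latents, cfg)

    def test_ntc_high_by_default(self, small_config):
        parts, latents = simulate_cohort(small_config)
        wells = simulate_qpcr_plates(parts, latents, small_config)
        ntc = wells[wells["role"] == "NTC"]
        assert (ntc["ct"] > 38.0).all()

    def test_determinism(self, small_config):
        parts, latents = simulate_cohort(small_config)
        out = []
        for _ in range(2):
            buf = io.StringIO()
            write_plates_csv(simulate_qpcr_plates(parts, latents, small_config), buf)
            out.append(buf.getvalue())
        assert out[0] == out[1]

    def test_variance_share_recovery_single_cohort(self, default_config):
        # loose single-cohort sanity; the tight 10-cohort mean check is in
        # the acceptance suite
        parts, latents = simulate_cohort(default_config)
        wells = simulate_qpcr_plates(parts, latents, default_config)
        kept, _ = qpcr_quant.qc_filter(wells)
        ddct = qpcr_quant.compute_ddct(kept)
        covs = parts.set_index("id").loc[
            ddct["sample_id"], ["dna_conc_ng_ul"]].rename(
            columns={"dna_conc_ng_ul": "dna_concentration"})
        covs.index = ddct.index
        covs["ct_threshold"] = wells.drop_duplicates("plate_id").set_index(
            "plate_id").loc[ddct["plate_id"], "ct_threshold"].to_numpy()
        covs["batch_id"] = ddct["batch_id"].to_numpy()
        _, dec = qpcr_quant.residualize_cn(ddct["ddct"], covs)
        assert abs(dec.shares["ct_threshold"] - 0.45) < 0.15
        assert dec.shares["batch_id"] < 0.2
        assert dec.shares["dna_concentration"] < 0.1


class TestSimulateDepth:
    def test_profile_lengths(self, small_config):
        parts, latents = simulate_cohort(small_config)
        profiles = simulate_depth_profiles(parts, latents, small_config,
                                           subset=list(parts["id"][:3]))
        assert len(profiles) == 3
        for profs in profiles.values():
            assert len(profs["MT"]) == MT_LENGTH
            assert len(profs["chr20"]) == small_config.nuclear_region_length

    def test_determinism(self, small_config):
        parts, latents = simulate_cohort(small_config)
        a = simulate_depth_profiles(parts, latents, small_config,
                                    subset=list(parts["id"][:2]))
        b = simulate_depth_profiles(parts, latents, small_config,
                                    subset=list(parts["id"][:2]))
        for sid in a:
            assert np.array_equal(a[sid]["MT"].depths, b[sid]["MT"].depths)


class TestSimulateGenotypes:
    def test_private_counts_exact(self):
        cfg = CohortConfig(total_snps=120, defining_snps_per_haplogroup=4,
                           private_snp_counts={"L": 15, "H": 3},
                           haplogroup_freqs={"L": 0.3, "H": 0.5, "U": 0.2},
                           seed=6)
        matrix, labels = simulate_mtdna_genotypes(90, cfg)
        assert matrix.n_variants == 120
        # defining SNPs are private to their haplogroup by construction
        assert len(private_variants(matrix, labels, "L")) == 15 + 4
        assert len(private_variants(matrix, labels, "H")) == 3 + 4
        assert len(private_variants(matrix, labels, "U")) == 4

    def test_single_haplogroup_no_foreign_private(self):
        cfg = CohortConfig(total_snps=30, defining_snps_per_haplogroup=2,
                           private_snp_counts={}, haplogroup_freqs={"H": 1.0},
                           seed=7)
        matrix, labels = simulate_mtdna_genotypes(20, cfg)
        assert set(labels) == {"H"}

    def test_grm_block_structure_two_groups(self):
        cfg = CohortConfig(total_snps=10, defining_snps_per_haplogroup=5,
                           private_snp_counts={},
                           haplogroup_freqs={"L": 0.5, "H": 0.5}, seed=8)
        matrix, labels = simulate_mtdna_genotypes(10, cfg)
        from mtcn.mito_popgen import haploid_grm
        grm = haploid_grm(matrix).values
        same = np.equal.outer(list(labels), list(labels))
        off_diag = ~np.eye(len(labels), dtype=bool)
        assert (grm[same & off_diag] > 0).all()
        assert (grm[~same] < 0).all()

    def test_empty_frequency_table_errors(self):
        with pytest.raises(CohortConfigError, match="empty"):
            simulate_mtdna_genotypes(10, CohortConfig(haplogroup_freqs={}))

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(CohortConfigError, match="sum"):
            simulate_mtdna_genotypes(
                10, CohortConfig(haplogroup_freqs={"H": 0.5, "L": 0.1}))

    def test_too_many_snps_for_defining_and_private(self):
        cfg = CohortConfig(total_snps=5, defining_snps_per_haplogroup=5,
                           private_snp_counts={"L": 10},
                           haplogroup_freqs={"L": 0.5, "H": 0.5})
        with pytest.raises(CohortConfigError, match="below"):
            simulate_mtdna_genotypes(10, cfg)

    def test_positions_unique_within_mt(self):
        cfg = CohortConfig(total_snps=200, seed=9)
        matrix, _ = simulate_mtdna_genotypes(30, cfg)
        assert len(set(matrix.positions)) == 200
        assert matrix.positions.min() >= 1
        assert matrix.positions.max() <= MT_LENGTH


class TestSimulatePhenotypes:
    def test_prevalence_one_flags_everyone(self):
        cfg = CohortConfig(
            group_sizes={"G1/HS": 10, "G1/CTRL": 10},
            ptsd_prevalence={"G1/HS": 1.0, "G1/CTRL": 0.0},
            blood_subset_size=5, seed=10)
        parts, latents = simulate_cohort(cfg)
        pclc, _ = simulate_phenotypes(parts, latents, cfg)
        item_cols = [c for c in pclc.columns if c.startswith("item_")]
        merged = parts.merge(pclc, left_on="id", right_on="participant_id")
        for _, row in merged.iterrows():
            resp = score_pclc(row[item_cols], row["id"])
            assert resp.probable_ptsd == (row["group"] == "HS")

    def test_blood_subset_size_70(self, default_config):
        parts, latents = simulate_cohort(default_config)
        _, blood = simulate_phenotypes(parts, latents, default_config)
        assert len(blood) == 70

    def test_item_scale_respected(self, small_config):
        parts, latents = simulate_cohort(small_config)
        pclc, _ = simulate_phenotypes(parts, latents, small_config)
        items = pclc[[c for c in pclc.columns if c.startswith("item_")]]
        assert items.shape[1] == 17
        assert items.min().min() >= 0
        assert items.max().max() <= 5

    def test_subset_larger_than_cohort_errors(self):
        cfg = CohortConfig(group_sizes={"G1/HS": 5}, blood_subset_size=10,
                           seed=11)
        parts, latents = simulate_cohort(cfg)
        with pytest.raises(CohortConfigError, match="subset"):
            simulate_phenotypes(parts, latents, cfg)

    def test_sex_effect_recovery_large_n(self):
        # configured 1.0 SD male effect on RBC recovered by OLS within 3 SE
        cfg = CohortConfig(
            group_sizes={"G2/HS": 300, "G2/CTRL": 300}, n_plates=40,
            blood_subset_size=600, linked_fraction=0.0,
            blood_sex_effects={"RBC_x10.12_per_L": 1.0}, seed=12)
        parts, latents = simulate_cohort(cfg)
        _, blood = simulate_phenotypes(parts, latents, cfg)
        merged = blood.merge(parts, left_on="participant_id", right_on="id")
        male = (merged["sex"] == "M").to_numpy(dtype=float)
        y = merged["RBC_x10.12_per_L"].to_numpy()
        y = (y - y.mean()) / 0.4  # configured measure SD
        X = np.column_stack([np.ones_like(male), male])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        se = np.sqrt(resid @ resid / (len(y) - 2)
                     * np.linalg.inv(X.T @ X)[1, 1])
        assert abs(beta[1] - 1.0) < 3 * se
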