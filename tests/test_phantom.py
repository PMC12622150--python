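"""Phantom generator: rendering fidelity, determinism, effect calibration,
placement constraints, presets, and the synthetic Ct tables."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi
from scipy.stats import ks_2samp

from nucleovol import (
    ChannelSpec,
    NoiseModel,
    PhantomDesign,
    QpcrDesign,
    make_ct_table,
    make_plate_phantom,
    study_presets,
    plate_truth,
    qpcr_study_preset,
)
from nucleovol.phantom import PhantomGenerationError

from phantom_oracles import clean_design, dapi_threshold


class TestRendering:
    def test_noise_free_supports_match_truth(self):
        """With no blur/noise the DAPI channel carries exactly one disjoint
        ellipsoidal support per planted nucleus, with voxel counts tracking
        the true volumes up to discretization."""
        design = clean_design(seed=3, cells=3, foci=(0, 0))
        stacks, truth = make_plate_phantom(design)
        (_, grid), = stacks.items()
        mask = grid.channel("DAPI") > dapi_threshold(design)
        labels, n = ndi.label(mask, structure=np.ones((3, 3, 3)))
        assert n == 3
        voxvol = grid.voxel_volume_um3
        counts = np.sort(np.bincount(labels.ravel())[1:])
        true_vols = np.sort(truth.cells.volume_um3.to_numpy())
        assert np.all(np.abs(counts * voxvol - true_vols) / true_vols < 0.08)

    def test_fixed_seed_is_bit_identical(self):
        design = clean_design(seed=7, cells=4, noise=NoiseModel(read_sd=2.0, shot=True),
                              psf_sigma_um=0.2)
        s1, t1 = make_plate_phantom(design)
        s2, t2 = make_plate_phantom(design)
        for key in s1:
            for ch in s1[key].channels:
                np.testing.assert_array_equal(s1[key].channels[ch], s2[key].channels[ch])
        pd.testing.assert_frame_equal(t1.cells, t2.cells)
        pd.testing.assert_frame_equal(t1.foci, t2.foci)

    def test_foci_centers_inside_owner_nucleus(self):
        design = clean_design(seed=11, cells=6)
        truth = plate_truth(design)
        merged = truth.foci.merge(
            truth.cells, on=["well", "field", "cell_id"], suffixes=("", "_cell")
        )
        q = (
            ((merged.cz_um - merged.cz_um_cell) / merged.rz_um) ** 2
            + ((merged.cy_um - merged.cy_um_cell) / merged.ry_um) ** 2
            + ((merged.cx_um - merged.cx_um_cell) / merged.rx_um) ** 2
        )
        assert len(merged) == len(truth.foci)
        assert (q <= 1.0).all()

    def test_cell_ids_unique_within_field(self):
        truth = plate_truth(clean_design(seed=5, cells=8))
        assert not truth.cells.duplicated(["well", "field", "cell_id"]).any()


class TestEffects:
    def test_volume_factor_calibrated_in_truth(self):
        """An injected nuclear-volume factor of 1.15 (the sustained-induction
        effect size) is reproduced by the generator's own ground truth to
        within 0.02 over ~500 cells per condition."""
        design = clean_design(
            seed=21, cells=100, conditions=("EV", "mutant-48h"),
            wells_per_condition=1, image_shape=(12, 1024, 1024),
        )
        design = dataclasses.replace(
            design, fields_per_well=5,
            effect_table={("mutant-48h", "nuclear_volume"): 1.15},
        )
        truth = plate_truth(design)
        means = truth.cells.groupby("condition").volume_um3.mean()
        ratio = means["mutant-48h"] / means["EV"]
        assert abs(ratio - 1.15) < 0.02

    @pytest.mark.parametrize(
        "quantity,column,transform",
        [
            ("focus_area", "radius_um", lambda r: r**2),
            ("focus_amplitude", "amplitude_factor", lambda a: a),
        ],
    )
    def test_focus_factors_land_on_truth(self, quantity, column, transform):
        f = 1.3
        design = clean_design(
            seed=22, cells=60, conditions=("EV", "mut"),
            image_shape=(12, 768, 768),
            effect_table={("mut", quantity): f},
        )
        truth = plate_truth(design)
        g = truth.foci.groupby("condition")[column].apply(
            lambda s: transform(s.to_numpy()).mean()
        )
        assert g["mut"] / g["EV"] == pytest.approx(f, rel=0.05)

    def test_control_wells_statistically_exchangeable(self):
        design = clean_design(seed=31, cells=80, wells_per_condition=3,
                              image_shape=(12, 768, 768))
        truth = plate_truth(design)
        by_well = {w: s.volume_um3.to_numpy() for w, s in truth.cells.groupby("well")}
        wells = sorted(by_well)
        for a, b in zip(wells, wells[1:]):
            assert ks_2samp(by_well[a], by_well[b]).pvalue > 0.01


class TestValidation:
    def test_placement_failure_is_explicit_and_names_the_field(self):
        design = clean_design(seed=1, cells=14, image_shape=(10, 128, 128),
                              min_center_spacing_um=10.0, max_place_attempts=500)
        with pytest.raises(PhantomGenerationError, match=r"W001 field 0"):
            plate_truth(design)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(cells_per_field=0),
            dict(nuclear_radius_um=(3.0, -0.1)),
            dict(min_center_spacing_um=0.0),
            dict(effect_table={("EV", "nuclear_volume"): 1.2}),  # control must stay 1
            dict(effect_table={("EV", "bogus_quantity"): 1.0}),
            dict(effect_table={("nope", "nuclear_volume"): 1.2}),
            dict(dapi_channel="missing"),
        ],
    )
    def test_invalid_designs_rejected(self, kw):
        with pytest.raises(ValueError):
            dataclasses.replace(clean_design(seed=0), **kw).validate()

    def test_infeasible_packing_rejected_upfront(self):
        with pytest.raises(ValueError, match="too small"):
            clean_design(seed=0, cells=500, image_shape=(10, 100, 100)).validate()


class TestPresets:
    @pytest.mark.parametrize(
        "model,mutation,quantity,factor",
        [
            ("SH-SY5Y-1h", "P301S", "nuclear_volume", 1.025),
            ("SH-SY5Y-1h", "P301S", "focus_area", 1.10),
            ("SH-SY5Y-1h", "P301S", "focus_amplitude", 2.0),
            ("SH-SY5Y-1h", "S305N", "focus_amplitude", 2.4),
            ("SH-SY5Y-1h", "S305N", "nuclear_volume", 1.027),
            ("iPSC", "IVS10+16", "nuclear_volume", 1.45),
            ("iPSC", "P301S", "nuclear_volume", 1.52),
        ],
    )
    def test_reported_effect_sizes_encoded(self, model, mutation, quantity, factor):
        design = study_presets(model, mutation)
        assert design.factor(mutation, quantity) == pytest.approx(factor)
        assert design.conditions[0] != mutation  # control first
        design.validate()

    def test_unknown_pair_lists_valid_options(self):
        with pytest.raises(ValueError, match="SH-SY5Y-1h/P301S"):
            study_presets("SH-SY5Y-1h", "R406W")

    @pytest.mark.parametrize(
        "model,mutation,gene,fold",
        [
            ("SH-SY5Y-1h", "P301S", "45S", 1.51),
            ("SH-SY5Y-1h", "S305N", "45S", 2.34),
            ("SH-SY5Y-1h", "P301S", "28S", 1.43),
            ("iPSC", "IVS10+16", "45S", 2.03),
        ],
    )
    def test_qpcr_presets_encode_reported_folds(self, model, mutation, gene, fold):
        design = qpcr_study_preset(model, mutation)
        assert design.ratio(mutation, gene) == pytest.approx(fold)
        design.validate()


class TestCtTables:
    def test_noise_free_ct_is_closed_form(self):
        design = QpcrDesign(
            conditions=["EV", "mut"],
            target_genes=["45S"],
            abundance_ratio={("mut", "45S"): 1.51},
            ct_noise_sd=0.0,
            seed=1,
        )
        table, folds = make_ct_table(design)
        ct = table.set_index(["condition", "gene"]).sort_index().ct
        assert set(ct.loc[("mut", "45S")]) == {design.baseline("45S") - math.log2(1.51)}
        assert set(ct.loc[("EV", "45S")]) == {design.baseline("45S")}
        # reference genes drift-free
        for ref in design.reference_genes:
            assert table[table.gene == ref].ct.nunique() == 1
        assert folds[("mut", "45S")] == 1.51

    def test_null_design_identical_ct_across_conditions(self):
        design = QpcrDesign(conditions=["EV", "a", "b"], ct_noise_sd=0.0)
        table, _ = make_ct_table(design)
        assert (table.groupby("gene").ct.nunique() == 1).all()

    def test_deterministic_for_fixed_seed(self):
        design = QpcrDesign(seed=9, ct_noise_sd=0.2)
        t1, _ = make_ct_table(design)
        t2, _ = make_ct_table(design)
        pd.testing.assert_frame_equal(t1, t2)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(replicates_per_sample=1),
            dict(ct_noise_sd=-0.1),
            dict(baseline_ct={"45S": 46.0}),
            dict(abundance_ratio={("P301S", "45S"): -2.0}),
            dict(abundance_ratio={("P301S", "ACTB"): 1.4}),  # reference must stay 1
            dict(abundance_ratio={("EV", "45S"): 1.4}),  # control must stay 1
        ],
    )
    def test_invalid_qpcr_designs_rejected(self, kw):
        with pytest.raises(ValueError):
            dataclasses.replace(QpcrDesign(), **kw).validate()
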