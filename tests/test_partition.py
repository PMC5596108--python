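"""Presence/absence, Venn partitioning, and habitat-breadth classification."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from nodulebiome import (
    CountTable,
    SampleFrame,
    class_summary,
    classify_otus,
    filter_table,
    presence_matrix,
    shared_among,
    venn_partition,
)
from nodulebiome.containers import default_scheme
from nodulebiome.partition import PresenceMatrix
from nodulebiome.simulate import generate_community

from conftest import brute_presence


def _frame_for(scheme, samples_per_stratum=2):
    rows = []
    for st in scheme.strata:
        for i in range(samples_per_stratum):
            rows.append(
                {"sample_id": f"{st.label}.{i + 1}", "habitat": st.habitat,
                 "stratum": st.label, "area": "A"}
            )
    return SampleFrame(pd.DataFrame(rows).set_index("sample_id"))


def _presence_from(det: pd.DataFrame) -> PresenceMatrix:
    return PresenceMatrix(detected=det, min_count=1, min_samples=1)


SCHEME = default_scheme()


def test_single_read_detection(tiny_scheme):
    frame = _frame_for(tiny_scheme)
    counts = pd.DataFrame(
        0, index=["o1"], columns=frame.sample_ids, dtype=int
    )
    counts.loc["o1", "epipelagic.1"] = 1
    pres = presence_matrix(CountTable(counts), frame, tiny_scheme)
    assert pres.detected.loc["o1", "epipelagic"]
    assert not pres.detected.loc["o1", ["sed_0_5", "nodule"]].any()


def test_min_count_threshold_drops_otu(tiny_scheme):
    frame = _frame_for(tiny_scheme)
    counts = pd.DataFrame(0, index=["o1"], columns=frame.sample_ids, dtype=int)
    counts.loc["o1", "epipelagic.1"] = 1
    pres = presence_matrix(CountTable(counts), frame, tiny_scheme, min_count=2)
    assert pres.dropped_otus == ["o1"]
    assert "o1" not in pres.detected.index


def test_presence_matches_brute_force(tiny_scheme):
    rng = np.random.default_rng(19)
    frame = _frame_for(tiny_scheme, samples_per_stratum=3)
    counts = pd.DataFrame(
        rng.integers(0, 4, size=(20, len(frame.sample_ids))),
        index=[f"o{i}" for i in range(20)], columns=frame.sample_ids,
    )
    for mc, ms in [(1, 1), (2, 1), (1, 2), (2, 2)]:
        pres = presence_matrix(CountTable(counts), frame, tiny_scheme,
                               min_count=mc, min_samples=ms)
        strata_map = frame.data["stratum"].to_dict()
        expected = brute_presence(counts, strata_map, tiny_scheme.labels, mc, ms)
        expected = expected.loc[expected.any(axis=1)]
        pd.testing.assert_frame_equal(pres.detected, expected.loc[pres.detected.index])
        assert set(pres.detected.index) == set(expected.index)


def test_min_count_monotonicity(tiny_scheme):
    rng = np.random.default_rng(7)
    frame = _frame_for(tiny_scheme, samples_per_stratum=3)
    counts = pd.DataFrame(
        rng.integers(0, 5, size=(30, len(frame.sample_ids))),
        index=[f"o{i}" for i in range(30)], columns=frame.sample_ids,
    )
    prev = None
    for mc in (1, 2, 3, 4):
        pres = presence_matrix(CountTable(counts), frame, tiny_scheme, min_count=mc)
        totals = pres.detected.reindex(
            index=[f"o{i}" for i in range(30)], fill_value=False
        ).sum()
        if prev is not None:
            assert (totals <= prev).all()
        prev = totals


def test_empty_stratum_reported(tiny_scheme):
    frame = _frame_for(tiny_scheme)
    keep = [s for s in frame.sample_ids if not s.startswith("nodule")]
    counts = pd.DataFrame(1, index=["o1"], columns=keep, dtype=int)
    pres = presence_matrix(CountTable(counts), frame.subset(keep), tiny_scheme)
    assert pres.empty_strata == ["nodule"]
    assert not pres.detected["nodule"].any()


# ---------------------------------------------------------------------------
# Venn


def test_venn_exclusive_regions():
    det = pd.DataFrame(
        {
            "epipelagic": [True, False, False],
            "sed_0_5": [False, True, False],
            "nodule": [False, False, True],
        },
        index=["w", "s", "n"],
    ).reindex(columns=SCHEME.labels, fill_value=False)
    venn = venn_partition(_presence_from(det), SCHEME)
    assert venn.region_counts["water"] == 1
    assert venn.region_counts["sediment"] == 1
    assert venn.region_counts["nodule"] == 1
    assert venn.region_counts["water&sediment&nodule"] == 0


def test_venn_everywhere_otu_in_triple_intersection():
    det = pd.DataFrame(
        [[True] * len(SCHEME.labels)], index=["o"], columns=SCHEME.labels
    )
    venn = venn_partition(_presence_from(det), SCHEME)
    assert venn.region_counts["water&sediment&nodule"] == 1


def test_venn_matches_set_enumeration_oracle():
    rng = np.random.default_rng(3)
    det = pd.DataFrame(
        rng.random(size=(100, len(SCHEME.labels))) < 0.3,
        index=[f"o{i}" for i in range(100)], columns=SCHEME.labels,
    )
    det = det.loc[det.any(axis=1)]
    venn = venn_partition(_presence_from(det), SCHEME)
    habs = {"water", "sediment", "nodule"}
    region_oracle: dict[frozenset, int] = {}
    for otu in det.index:
        present = frozenset(
            SCHEME.habitat_of(st) for st in SCHEME.labels if det.loc[otu, st]
        )
        region_oracle[present] = region_oracle.get(present, 0) + 1
    for key, count in venn.region_counts.items():
        members = frozenset(key.split("&"))
        assert count == region_oracle.get(members, 0)
    assert sum(venn.region_counts.values()) == len(det)
    # pairwise shared = sum of the two regions containing both habitats
    for h1, h2 in [("water", "sediment"), ("water", "nodule"), ("sediment", "nodule")]:
        expected = sum(c for k, c in region_oracle.items() if {h1, h2} <= k)
        assert venn.pairwise_shared[f"{h1}&{h2}"] == expected


def test_shared_among_with_absence_constraint():
    det = pd.DataFrame(
        {
            "sed_0_5": [True, True],
            "sed_5_6": [True, False],
            "nodule": [True, True],
        },
        index=["a", "b"],
    ).reindex(columns=SCHEME.labels, fill_value=False)
    pres = _presence_from(det)
    assert shared_among(pres, ["sed_0_5", "nodule"]) == 2
    assert shared_among(pres, ["sed_0_5", "sed_5_6", "nodule"]) == 1
    assert shared_among(pres, ["sed_0_5", "nodule"], absent_from=["sed_5_6"]) == 1


# ---------------------------------------------------------------------------
# classification


def _det_single(stratum):
    det = pd.DataFrame(False, index=["o"], columns=SCHEME.labels)
    det.loc["o", stratum] = True
    return det


def test_single_stratum_otu_is_specialist():
    cls = classify_otus(_presence_from(_det_single("sed_8_10")), SCHEME)
    assert cls.labels["o"] == "specialist"
    assert cls.specialist_stratum["o"] == "sed_8_10"
    assert cls.specialist_habitat["o"] == "sediment"


def test_everywhere_otu_is_generalist_under_both_rules():
    det = pd.DataFrame([[True] * len(SCHEME.labels)], index=["o"], columns=SCHEME.labels)
    for rule in ("strict", "operative"):
        cls = classify_otus(_presence_from(det), SCHEME, rule_set=rule)
        assert cls.labels["o"] == "generalist"


def test_epipelagic_plus_nodule_is_moderate_generalist():
    det = pd.DataFrame(False, index=["o"], columns=SCHEME.labels)
    det.loc["o", ["epipelagic", "nodule"]] = True
    cls = classify_otus(_presence_from(det), SCHEME)
    assert cls.labels["o"] == "moderate_generalist"


def test_core_set_generalist_not_strict_generalist():
    # present in all water zones, nodules, and sediment <= 6 cm only
    det = pd.DataFrame(False, index=["o"], columns=SCHEME.labels)
    det.loc["o", ["epipelagic", "mesopelagic", "bathypelagic", "abyssopelagic",
                  "sed_0_5", "sed_5_6", "nodule"]] = True
    assert classify_otus(_presence_from(det), SCHEME,
                         rule_set="operative").labels["o"] == "generalist"
    assert classify_otus(_presence_from(det), SCHEME,
                         rule_set="strict").labels["o"] == "moderate_generalist"


def test_multi_stratum_single_habitat_is_unclassified():
    det = pd.DataFrame(False, index=["o"], columns=SCHEME.labels)
    det.loc["o", ["sed_0_5", "sed_8_10"]] = True
    cls = classify_otus(_presence_from(det), SCHEME)
    assert cls.labels["o"] == "unclassified"


def test_labels_form_a_partition():
    rng = np.random.default_rng(8)
    det = pd.DataFrame(
        rng.random(size=(200, len(SCHEME.labels))) < 0.25,
        index=[f"o{i}" for i in range(200)], columns=SCHEME.labels,
    )
    det = det.loc[det.any(axis=1)]
    cls = classify_otus(_presence_from(det), SCHEME)
    assert set(cls.labels.unique()) <= {
        "specialist", "moderate_generalist", "generalist", "unclassified"
    }
    assert len(cls.labels) == len(det)
    spec = cls.labels.index[cls.labels == "specialist"]
    assert (det.loc[spec].sum(axis=1) == 1).all()


def test_noise_free_recovery_of_planted_labels(small_params):
    p = replace(small_params, off_habitat_epsilon=0.0, export_fraction=0.0,
                depth_mean=20000, depth_sd=1)
    table, frame, truth = generate_community(p)
    filtered = filter_table(table, frame)
    frame_nc = frame.subset([s for s in frame.noncontrol_samples()])
    pres = presence_matrix(filtered, frame_nc, p.strata)
    cls = classify_otus(pres, p.strata)
    planted = {o: c for o, c in truth.planted_class.items()
               if c in ("specialist", "moderate_generalist", "generalist")}
    assert set(cls.labels.index) == set(planted)
    for otu, expected in planted.items():
        assert cls.labels[otu] == expected, otu


# ---------------------------------------------------------------------------
# class_summary


def test_all_specialists_contribute_all_sequences(tiny_scheme):
    frame = _frame_for(tiny_scheme)
    counts = pd.DataFrame(0, index=["o1", "o2"], columns=frame.sample_ids, dtype=int)
    counts.loc["o1", "epipelagic.1"] = 10
    counts.loc["o2", "sed_0_5.2"] = 30
    table = CountTable(counts)
    pres = presence_matrix(table, frame, tiny_scheme)
    cls = classify_otus(pres, tiny_scheme, occupancy_table=table, frame=frame)
    summary = class_summary(cls, table, frame)
    assert summary.per_class.loc["specialist", "pct_sequences"] == pytest.approx(100.0)
    assert summary.per_class["pct_sequences"].sum() == pytest.approx(100.0)


def test_occupancy_fraction(tiny_scheme):
    frame = _frame_for(tiny_scheme, samples_per_stratum=5)  # 15 samples
    counts = pd.DataFrame(0, index=["o1"], columns=frame.sample_ids, dtype=int)
    counts.iloc[0, :9] = 1
    table = CountTable(counts)
    pres = presence_matrix(table, frame, tiny_scheme)
    cls = classify_otus(pres, tiny_scheme, occupancy_table=table, frame=frame)
    assert cls.occupancy["o1"] == pytest.approx(9 / 15)


def test_planted_class_sequence_fractions_recovered(tiny_scheme):
    # per-class sequence shares should track the planted mixing weights
    deviations = []
    for seed in range(10):
        p = replace_params(tiny_scheme, seed)
        table, frame, truth = generate_community(p)
        filtered = filter_table(table, frame)
        frame_nc = frame.subset(frame.noncontrol_samples())
        pres = presence_matrix(filtered, frame_nc, tiny_scheme)
        cls = classify_otus(pres, tiny_scheme)
        summary = class_summary(cls, filtered, frame_nc)
        lat = truth.latent
        rel = lat / lat.sum(axis=0)
        planted_share = {}
        for label in ("specialist", "moderate_generalist", "generalist"):
            otus = [o for o, c in truth.planted_class.items() if c == label]
            planted_share[label] = rel.loc[otus].sum(axis=0).mean() * 100
        for label, share in planted_share.items():
            deviations.append(
                abs(summary.per_class.loc[label, "pct_sequences"] - share)
            )
    assert np.mean(deviations) < 2.0


def replace_params(scheme, seed):
    from nodulebiome import SimParams

    return SimParams(
        strata=scheme, n_areas=1, samples_per_stratum_per_area=6,
        n_specialist_otus_per_stratum=20, n_moderate_otus=40,
        n_generalist_otus=10, n_contaminant_otus=0, n_decoy_otus=0,
        export_fraction=0.0, off_habitat_epsilon=0.0, depth_mean=8000,
        depth_sd=500, seed=seed,
    )
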