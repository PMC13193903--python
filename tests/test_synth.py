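"""Synthetic generator: round trips, determinism, hierarchy, mixtures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ifcmorph.classes import CLASS_ORDER, MorphClass, assign_label
from ifcmorph.synth import (
    CellParams,
    DomainParams,
    HierarchySpec,
    cell_layout,
    default_domains,
    generate_cell,
    generate_dataset,
    render_cell_image,
    render_record,
    sample_cell_params,
    sample_defects,
    write_images,
)


# ---------------------------------------------------------------------------
# single-cell generation


def test_normal_cell_has_empty_defect_set():
    _, d = generate_cell(MorphClass.NM, rng_seed=0)
    assert d.is_normal


def test_ctm_cell_round_trips_through_label_assignment():
    _, d = generate_cell(MorphClass.CTM, rng_seed=1)
    assert "coiled_tail_midpiece" in d.defects
    assert assign_label(d) is MorphClass.CTM


@pytest.mark.parametrize("cls", list(MorphClass))
def test_every_class_round_trips_over_many_seeds(cls):
    rng = np.random.default_rng(100)
    for _ in range(100):
        d = sample_defects(cls, rng)
        assert assign_label(d) is cls
    # full image path for a handful of seeds
    for seed in range(3):
        img, d = generate_cell(cls, rng_seed=seed)
        assert assign_label(d) is cls
        assert img.dtype == np.uint8 and img.shape == (96, 96)


def test_generate_cell_rejects_unknown_class():
    with pytest.raises(ValueError):
        generate_cell("NOTACLASS", rng_seed=0)


def test_generation_is_deterministic_and_seed_sensitive():
    a, _ = generate_cell(MorphClass.AT, rng_seed=5)
    b, _ = generate_cell(MorphClass.AT, rng_seed=5)
    c, _ = generate_cell(MorphClass.AT, rng_seed=6)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_proximal_droplet_renders_in_proximal_half():
    """Bright-blob detection on the rendered frame recovers the droplet
    position on the head-side half of the midpiece."""
    dom = DomainParams(noise_sd=2.0)
    for seed in range(2, 7):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
        d = sample_defects(MorphClass.PCD, rng)
        p = sample_cell_params(MorphClass.PCD, dom, rng)
        img = render_cell_image(p, d, dom, rng)
        assert p.droplet_position < 0.5
        ys, xs = np.nonzero(img >= 244)  # droplet disc is the only bright blob
        assert len(xs) >= 3, "droplet blob not found"
        centroid = np.array([xs.mean(), ys.mean()])
        lay = cell_layout(p)
        along = float((lay["neck"] - centroid) @ lay["u"])  # px behind neck
        assert along < 0.5 * lay["mid_len"] + 1.5


def test_cell_params_validation():
    with pytest.raises(ValueError):
        CellParams(head_length_px=-1.0)
    with pytest.raises(ValueError):
        CellParams(droplet_position=1.5)


def test_domain_params_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        DomainParams(class_mixture=np.full(10, 0.2))
    with pytest.raises(ValueError, match="noise_sd"):
        DomainParams(noise_sd=-1.0)


# ---------------------------------------------------------------------------
# dataset generation


def test_row_count_matches_design_product():
    h = HierarchySpec(
        n_bulls=2,
        ejaculates_per_bull={"fresh": 1},
        files_per_ejaculate=1,
        events_per_file=30,
        seed=1,
    )
    m = generate_dataset(h)
    assert len(m) == 2 * 1 * 1 * 30
    assert set(m["bull_id"].unique()) == {"B00", "B01"}


def test_empty_design_yields_empty_manifest_with_schema():
    m0 = generate_dataset(HierarchySpec(n_bulls=0))
    m1 = generate_dataset(
        HierarchySpec(n_bulls=1, ejaculates_per_bull={"fresh": 1},
                      files_per_ejaculate=1, events_per_file=5)
    )
    assert len(m0) == 0
    assert list(m0.columns) == list(m1.columns)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        HierarchySpec(n_bulls=-1)


def test_manifest_is_deterministic():
    h = HierarchySpec(n_bulls=2, ejaculates_per_bull={"fresh": 1},
                      files_per_ejaculate=1, events_per_file=40, seed=9)
    assert generate_dataset(h).equals(generate_dataset(h))


def test_label_mixture_matches_specification():
    """Chi-square goodness of fit of drawn labels vs the domain mixture."""
    h = HierarchySpec(n_bulls=1, ejaculates_per_bull={"fresh": 1},
                      files_per_ejaculate=1, events_per_file=10_000, seed=3)
    doms = default_domains(0.0)
    m = generate_dataset(h, doms, include_params=False)
    mix = doms[0].class_mixture
    observed = m["label"].value_counts()
    obs = np.array([observed.get(c.value, 0) for c in CLASS_ORDER])
    res = stats.chisquare(obs, f_exp=mix * len(m))
    assert res.pvalue > 0.01


def test_bull_effects_induce_intra_bull_correlation():
    """One-way random-effects ICC of head length is clearly positive with
    bull effects on, and near zero with them off."""

    def icc(sd):
        h = HierarchySpec(n_bulls=8, ejaculates_per_bull={"fresh": 1},
                          files_per_ejaculate=1, events_per_file=300,
                          bull_effect_sd=sd, ejaculate_effect_sd=0.0, seed=21)
        # zero domain shift so breed morphometry offsets cannot masquerade
        # as bull effects
        m = generate_dataset(h, default_domains(0.0))
        groups = [g["head_length_px"].to_numpy()
                  for _, g in m.groupby("bull_id", observed=True)]
        k = len(groups[0])
        grand = np.concatenate(groups).mean()
        msb = k * sum((g.mean() - grand) ** 2 for g in groups) / (len(groups) - 1)
        msw = np.mean([g.var(ddof=1) for g in groups])
        return (msb - msw) / (msb + (k - 1) * msw)

    assert icc(0.15) > 0.3
    assert abs(icc(0.0)) < 0.05


def test_conditions_assign_seasons_to_ejaculates():
    h = HierarchySpec(n_bulls=1, ejaculates_per_bull={"fresh": 2, "frozen": 1},
                      files_per_ejaculate=1, events_per_file=5, seed=0)
    m = generate_dataset(h)
    seasons = m.groupby("ejaculate_id", observed=True)["season"].first()
    assert sorted(seasons) == ["fall", "spring", "summer"]
    frozen = m[m["condition"] == "frozen"]
    assert (frozen["season"] == "summer").all()


def test_missing_domain_for_breed_condition_raises():
    doms = [DomainParams(breed="KW", condition="fresh")]
    h = HierarchySpec(n_bulls=1, ejaculates_per_bull={"frozen": 1},
                      files_per_ejaculate=1, events_per_file=5)
    with pytest.raises(KeyError):
        generate_dataset(h, doms)


def test_render_record_matches_manifest_and_pngs_round_trip(tmp_path):
    h = HierarchySpec(n_bulls=1, ejaculates_per_bull={"fresh": 1},
                      files_per_ejaculate=1, events_per_file=6, seed=4)
    doms = default_domains()
    m = generate_dataset(h, doms)
    img, d = render_record(m.iloc[0], doms)
    assert assign_label(d).value == m.iloc[0]["label"]
    out = write_images(m, tmp_path, doms)
    from ifcmorph.preprocess import load_image

    re_read = load_image(out.iloc[0]["path"])
    assert np.array_equal(re_read, img)
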