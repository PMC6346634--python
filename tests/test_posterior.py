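"""Posterior summarisation, CI-overlap classification and group summaries."""

import numpy as np
import pandas as pd
import pytest

from seedshadow.errors import ReferentialError, ValidationError
from seedshadow import posterior as post
from seedshadow.mcmc import PosteriorSamples
from seedshadow.model import FIXED_EFFECT_NAMES


def _samples(u_draws, beta_draws=None, regimes=("protected",)):
    u = np.asarray(u_draws, dtype=float)
    if u.ndim == 1:
        u = u[:, None]
    n = u.shape[0]
    beta = np.zeros((n, 4)) if beta_draws is None else np.asarray(beta_draws)
    return PosteriorSamples(
        species="X", regimes=list(regimes), years=np.array([1]),
        beta_names=FIXED_EFFECT_NAMES, u=u, beta=beta,
        sigma_a2=np.zeros(n), sigma_g2=np.zeros(n), sigma_e2=np.zeros(n),
        deviance=np.zeros(n), mean_rho=np.zeros(1), mean_f=np.zeros((1, 1)),
        mean_lambda=np.zeros((1, 1)), acceptance={}, center_log_dbh=0.0)


def test_summarize_degenerate_posterior():
    disp, _ = post.summarize_posterior(_samples(np.full(200, 100.0)))
    row = disp.iloc[0]
    assert row["mean_m"] == pytest.approx(15.708, abs=1e-3)
    assert row["ci_lo_m"] == pytest.approx(row["ci_hi_m"])


def test_summarize_two_point_posterior_mean():
    draws = np.array([100.0, 400.0] * 100)
    disp, _ = post.summarize_posterior(_samples(draws))
    assert disp.iloc[0]["mean_m"] == pytest.approx((15.708 + 31.416) / 2, abs=1e-3)


def test_percentile_convention_linear_interpolation():
    assert np.percentile(np.arange(1, 1001), 2.5) == pytest.approx(25.975)


def test_classify_overlap_printed_rows():
    # Celtis mildbraedii: logged CI clear of protected CI -> affected, higher
    prot = dict(species="C", regime="protected", mean_m=10.3, ci_lo_m=9.9, ci_hi_m=10.8)
    logg = dict(species="C", regime="logged", mean_m=20.1, ci_lo_m=18.7, ci_hi_m=21.6)
    hl = dict(species="C", regime="hunted_logged", mean_m=21.0, ci_lo_m=19.8, ci_hi_m=22.3)
    c = post.classify_overlap(prot, logg, hl)
    assert c["affected"] and c["direction"]["logged"] == "higher"
    # Lepidobotrys staudtii: logged hi 42.1 >= protected lo 41.9 -> overlap
    prot = dict(species="L", regime="protected", mean_m=45.7, ci_lo_m=41.9, ci_hi_m=49.4)
    logg = dict(species="L", regime="logged", mean_m=35.9, ci_lo_m=27.9, ci_hi_m=42.1)
    hl = dict(species="L", regime="hunted_logged", mean_m=51.1, ci_lo_m=47.9, ci_hi_m=54.3)
    c = post.classify_overlap(prot, logg, hl)
    assert c["direction"]["logged"] == "none"
    # hunted+logged [47.9, 54.3] still touches the protected CI -> no effect
    assert c["direction"]["hunted_logged"] == "none"
    assert not c["affected"]


def test_classify_overlap_identical_intervals_not_affected():
    rows = [dict(species="X", regime=r, mean_m=10.0, ci_lo_m=9.0, ci_hi_m=11.0)
            for r in ("protected", "logged", "hunted_logged")]
    c = post.classify_overlap(*rows)
    assert not c["affected"]


def test_classify_overlap_symmetric_and_scale_invariant():
    rng = np.random.default_rng(0)
    for _ in range(50):
        lo = rng.uniform(0, 50, size=3)
        hi = lo + rng.uniform(0.1, 20, size=3)
        mid = (lo + hi) / 2
        rows = [dict(species="X", regime=r, mean_m=m, ci_lo_m=l, ci_hi_m=h)
                for r, m, l, h in zip(("protected", "logged", "hunted_logged"), mid, lo, hi)]
        c1 = post.classify_overlap(*rows)
        scaled = [dict(r, mean_m=3 * r["mean_m"], ci_lo_m=3 * r["ci_lo_m"],
                       ci_hi_m=3 * r["ci_hi_m"]) for r in rows]
        c2 = post.classify_overlap(*scaled)
        assert c1["direction"] == c2["direction"]
        # overlap test symmetric in interval order
        assert post.intervals_overlap(lo[0], hi[0], lo[1], hi[1]) == \
            post.intervals_overlap(lo[1], hi[1], lo[0], hi[0])


def test_classify_overlap_malformed_interval():
    rows = [dict(species="X", regime=r, mean_m=10.0, ci_lo_m=9.0, ci_hi_m=11.0)
            for r in ("protected", "logged", "hunted_logged")]
    rows[1]["mean_m"] = 100.0
    with pytest.raises(ValidationError):
        post.classify_overlap(*rows)


def test_count_affected_empty_and_missing_trait():
    empty = pd.DataFrame(columns=["species", "affected", "logged", "hunted_logged"])
    traits = pd.DataFrame({"species": [], "vector": []})
    assert post.count_affected(empty, traits)["total"] == (0, 0)
    cls = pd.DataFrame({"species": ["X"], "affected": [True],
                        "logged": ["higher"], "hunted_logged": ["none"]})
    with pytest.raises(ReferentialError):
        post.count_affected(cls, traits)


def test_group_mean_single_cell_and_consistency():
    t1 = post.load_printed_table1()
    one = t1.iloc[[0]]
    assert post.group_mean_dispersal(one, "regime").iloc[0] == one["mean_m"].iloc[0]
    # mean over all cells equals the count-weighted mean of group means
    by_vec = t1.groupby("vector")["mean_m"].agg(["mean", "size"])
    overall = (by_vec["mean"] * by_vec["size"]).sum() / by_vec["size"].sum()
    assert overall == pytest.approx(t1["mean_m"].mean())
    with pytest.raises(ValidationError):
        post.group_mean_dispersal(t1, "nonsense")


def test_effect_sign_table_printed_rows():
    t2 = post.load_printed_table2()
    signs = post.effect_sign_table(t2).set_index(["species", "covariate"])["sign"]
    assert signs[("Albizia gummifera", "diameter")] == "positive"
    assert signs[("Grossera macrantha", "logging")] == "negative"
    assert signs[("Albizia gummifera", "logging")] == "null"


def test_printed_tables_shape():
    t1, t2 = post.load_printed_table1(), post.load_printed_table2()
    assert t1.shape[0] == 33 * 3 and t2.shape[0] == 33 * 3
    assert (t1["ci_lo_m"] <= t1["mean_m"]).all() and (t1["mean_m"] <= t1["ci_hi_m"]).all()
    assert t1.groupby("vector")["species"].nunique().to_dict() == \
        {"abiotic": 7, "animal": 18, "both": 8}
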