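import numpy as np
import pandas as pd
import pytest

from seedshadow.simulate import (GroundTruth, StandConfig, generate_stand,
                                 layout_traps, simulate_dataset)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def one_plot_dataset():
    """Single protected 1-ha plot, 3 years, ground truth retained."""
    trees, traps, counts, traits, truth = simulate_dataset(
        seed=1, n_plots_per_regime=1, regimes=("protected",))
    return trees, traps, counts, traits, truth


@pytest.fixture(scope="session")
def full_dataset():
    """Three regimes x 2 plots, 3 years — the default study conditions."""
    return simulate_dataset(seed=11)


@pytest.fixture()
def tiny_tables(tmp_path):
    """Minimal hand-written CSVs for the io readers."""
    trees = tmp_path / "trees.csv"
    trees.write_text(
        "plot_id,tree_id,species,x_m,y_m,dbh_cm,regime\n"
        "P1,T1,Celtis mildbraedii,10.0,20.0,25.0,protected\n"
        "P1,T2,Celtis mildbraedii,50.0,50.0,40.0,protected\n"
        "P1,T3,Celtis mildbraedii,80.0,30.0,15.0,protected\n")
    traps = tmp_path / "traps.csv"
    traps.write_text(
        "plot_id,trap_id,x_m,y_m,area_m2,season_fraction\n"
        "P1,S1,25.0,40.0,1.0,1.0\n"
        "P1,S2,50.0,40.0,1.0,0.5\n")
    counts = tmp_path / "seed_counts.csv"
    counts.write_text(
        "plot_id,trap_id,species,year,count\n"
        "P1,S1,Celtis mildbraedii,1,4\n"
        "P1,S2,Celtis mildbraedii,1,2\n"
        "P1,S1,Celtis mildbraedii,2,0\n"
        "P1,S2,Celtis mildbraedii,2,1\n")
    traits = tmp_path / "traits.csv"
    traits.write_text("species,vector\nCeltis mildbraedii,animal\n")
    return dict(trees=trees, traps=traps, counts=counts, traits=traits)
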