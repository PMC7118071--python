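import numpy as np
import pandas as pd
import pytest

from admixps.containers import HaplotypeMatrix, WeightTable


def make_weights(beta, chrom="1", start_pos=100, effect="G", other="A"):
    """WeightTable with evenly spaced positions and fixed non-palindromic alleles."""
    beta = np.asarray(beta, dtype=float)
    return WeightTable(
        table=pd.DataFrame(
            {
                "chrom": chrom,
                "pos": start_pos + 10 * np.arange(len(beta)),
                "effect_allele": effect,
                "other_allele": other,
                "beta": beta,
            }
        )
    )


def make_genos(states, chrom="1", start_pos=100, ref="A", alt="G", samples=None):
    """HaplotypeMatrix from a (2*n_ind, n_sites) state array; alt = effect allele."""
    states = np.asarray(states, dtype=np.int8)
    n_ind = states.shape[0] // 2
    if samples is None:
        samples = [f"S{i}" for i in range(n_ind)]
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start_pos + 10 * np.arange(states.shape[1]),
            "ref": ref,
            "alt": alt,
        }
    )
    return HaplotypeMatrix(samples=samples, sites=sites, states=states)


def random_cohort(rng, n_ind, n_sites, freq_low=0.1, freq_high=0.9):
    """Random iid-site phased cohort and matching weight table."""
    freqs = rng.uniform(freq_low, freq_high, n_sites)
    states = (rng.random((2 * n_ind, n_sites)) < freqs).astype(np.int8)
    beta = rng.standard_normal(n_sites)
    return make_genos(states), make_weights(beta), freqs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_sim_cohort():
    """The simulator under its default study conditions (seed 1)."""
    from admixps.synthetic_data import CohortConfig, simulate_admixed_cohort

    return simulate_admixed_cohort(CohortConfig(seed=1))


def shifted_cohort(rng, n_ind=80, n_sites=600, delta=0.06, n_ref=60):
    """Two-ancestry admixed cohort with a systematic B-vs-A frequency shift
    aligned with the effect signs, so scores built on B-ancestry segments
    are deterministically shifted upward relative to the A reference.

    Returns (genos, weights, mask, ref_panel); masks are iid 50/50.
    """
    from admixps.containers import AncestryMask

    beta = rng.standard_normal(n_sites)
    f_a = rng.uniform(0.2, 0.8, n_sites)
    f_b = np.clip(f_a + delta * np.sign(beta), 0.05, 0.95)
    labels = (rng.random((2 * n_ind, n_sites)) < 0.5).astype(np.int8)
    freqs = np.where(labels == 0, f_a, f_b)
    states = (rng.random((2 * n_ind, n_sites)) < freqs).astype(np.int8)
    genos = make_genos(states)
    mask = AncestryMask(ancestries=["A", "B"], hap_ids=genos.hap_ids, labels=labels)
    ref_states = (rng.random((2 * n_ref, n_sites)) < f_a).astype(np.int8)
    ref = make_genos(ref_states, samples=[f"R{i}" for i in range(n_ref)])
    return genos, make_weights(beta), mask, ref
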