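import numpy as np
import pytest

import hvarnet as hv


@pytest.fixture(scope="session")
def tiny_study():
    """Two-subject single-group study, small enough for fast Gibbs runs."""
    design = hv.BlockDesign(sessions=1, scans_per_session=48, block_length=12)
    truth = hv.make_default_truth(R=2, K=1, n_edges=1, effect_size=0.4, seed=42,
                                  design=design, subjects_per_group=2)
    study = hv.simulate_study(truth)
    return study


@pytest.fixture(scope="session")
def tiny_stack(tiny_study):
    return hv.build_study(tiny_study.series, tiny_study.truth.spec)


@pytest.fixture(scope="session")
def tiny_posterior(tiny_stack):
    return hv.run_gibbs(tiny_stack,
                        config=hv.SamplerConfig(iterations=600, burn_in=200,
                                                thin=2, seed=9))


def make_constant_posterior(spec, phi_draws, n_subjects=1, seed=0,
                            xi_draws=None):
    """Posterior container with prescribed phi draws (for network-logic
    tests that need exact control of the sample clouds)."""
    N = phi_draws.shape[0]
    rng = np.random.default_rng(seed)
    xi = (np.zeros((N, n_subjects, spec.q)) if xi_draws is None else xi_draws)
    return hv.PosteriorSamples(
        spec=spec,
        subject_ids=[f"sub{i + 1}" for i in range(n_subjects)],
        subject_groups=[spec.groups[0]] * n_subjects,
        config=hv.SamplerConfig(iterations=2 * N, burn_in=0, thin=2, seed=seed),
        hyper=hv.HyperParams(),
        phi=phi_draws, xi=xi,
        tau=np.abs(rng.normal(1.0, 0.1, size=(N, spec.R))) + 0.5,
        d=np.ones((N, spec.G, spec.q)) * 4.0,
        alpha=np.ones((N, spec.G * spec.q)),
        lambda2=np.ones(N), gamma=np.ones(N))
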