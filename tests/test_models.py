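import numpy as np
import pytest

from bedplane.geometry import Window
from bedplane.models import (FittedModel, GaussPoissonPairs, HomPoisson,
                             InhomPoisson, Thomas, _simulate_pair_groups,
                             fit_gauss_poisson_mincontrast, fit_hom_poisson,
                             fit_inhom_poisson, fit_thomas_mincontrast,
                             simulate_model, thomas_theoretical_k)
from bedplane.pattern_core import PointPattern
from bedplane.summaries import k_translation


@pytest.fixture(scope="module")
def w80():
    return Window.rectangle(0, 0, 8, 10)


# --------------------------------------------------------------------------- #
# spec validation

def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        HomPoisson(-1.0)
    with pytest.raises(ValueError):
        Thomas(0.0, 0.1, 1.0)
    with pytest.raises(ValueError):
        GaussPoissonPairs(1.0, 0.2, 1.5)


def test_implied_intensities():
    assert Thomas(0.49, 0.17, 1.84).implied_intensity == pytest.approx(0.9016)
    assert GaussPoissonPairs(0.52, 0.28, 0.75).implied_intensity == pytest.approx(0.91)


# --------------------------------------------------------------------------- #
# simulation

def test_hom_poisson_zero_intensity(w80):
    pat = simulate_model(HomPoisson(0.0), w80, seed=1)
    assert pat.n == 0


def test_hom_poisson_count(w80):
    counts = [simulate_model(HomPoisson(2.0), w80, seed=i).n for i in range(300)]
    mean = np.mean(counts)
    se = np.std(counts, ddof=1) / np.sqrt(len(counts))
    assert abs(mean - 160.0) < 3 * se


def test_thomas_mean_count_matches_table_parameters(w80):
    """κμ|W| = 0.49 · 1.84 · 80 ≈ 72.1 expected points."""
    counts = [simulate_model(Thomas(0.49, 0.17, 1.84), w80, seed=i).n
              for i in range(500)]
    mean = np.mean(counts)
    se = np.std(counts, ddof=1) / np.sqrt(len(counts))
    assert abs(mean - 0.49 * 1.84 * 80.0) < 3 * se


def test_pair_retention_fraction(w80):
    """Fraction of interior 2-point groups ≈ P over many seeds."""
    spec = GaussPoissonPairs(0.5, 0.25, 0.75)
    n2 = n_groups = 0
    for i in range(500):
        rng = np.random.default_rng(i)
        parents, pts, gid = _simulate_pair_groups(spec, w80, rng)
        # only parents whose full disc lies inside the window
        xmin, ymin, xmax, ymax = w80.bounds
        interior = ((parents[:, 0] > xmin + spec.radius)
                    & (parents[:, 0] < xmax - spec.radius)
                    & (parents[:, 1] > ymin + spec.radius)
                    & (parents[:, 1] < ymax - spec.radius))
        sizes = np.bincount(gid, minlength=len(parents))
        n_groups += interior.sum()
        n2 += (sizes[interior] == 2).sum()
    frac = n2 / n_groups
    se = np.sqrt(0.75 * 0.25 / n_groups)
    assert abs(frac - 0.75) < 3 * se


def test_gp_p1_only_pairs(w80):
    spec = GaussPoissonPairs(0.5, 0.25, 1.0)
    _, pts, gid = _simulate_pair_groups(spec, w80, np.random.default_rng(3))
    sizes = np.bincount(gid)
    assert np.all(sizes[sizes > 0] == 2)


def test_gp_p0_singletons(w80):
    spec = GaussPoissonPairs(0.5, 0.25, 0.0)
    _, pts, gid = _simulate_pair_groups(spec, w80, np.random.default_rng(3))
    sizes = np.bincount(gid)
    assert np.all(sizes[sizes > 0] == 1)


@pytest.mark.parametrize("spec,lam", [
    (HomPoisson(1.2), 1.2),
    (Thomas(0.5, 0.2, 2.0), 1.0),
    (GaussPoissonPairs(0.5, 0.25, 0.6), 0.8),
])
def test_simulated_intensity_matches_spec(spec, lam, w80):
    counts = [simulate_model(spec, w80, seed=i).n for i in range(500)]
    mean = np.mean(counts)
    se = np.std(counts, ddof=1) / np.sqrt(len(counts))
    assert abs(mean - lam * w80.area) < 3 * se


def test_buffer_independence(w80):
    """Expected count unchanged when the parent buffer is doubled."""
    spec = Thomas(0.5, 0.2, 2.0)
    c1 = [simulate_model(spec, w80, seed=i).n for i in range(400)]
    c2 = [simulate_model(spec, w80, seed=i, buffer=1.6).n for i in range(400)]
    se = np.sqrt(np.var(c1, ddof=1) / 400 + np.var(c2, ddof=1) / 400)
    assert abs(np.mean(c1) - np.mean(c2)) < 3 * se


def test_inhom_simulation_gradient(w80):
    spec = InhomPoisson(np.log(0.5), 0.3, 0.0)
    pats = [simulate_model(spec, w80, seed=i) for i in range(100)]
    xs = np.concatenate([p.xy[:, 0] for p in pats])
    # mean x must exceed the window midline under a positive x-gradient
    assert xs.mean() > 4.0


# --------------------------------------------------------------------------- #
# theoretical K

def test_thomas_k_zero_at_zero():
    k = thomas_theoretical_k(Thomas(0.49, 0.17, 1.84), np.array([0.0]))
    assert k.values[0] == 0.0


def test_thomas_k_csr_limit():
    r = np.linspace(0.1, 2.0, 20)
    k = thomas_theoretical_k(Thomas(1e6, 0.17, 1.0), r)
    assert np.allclose(k.values, np.pi * r ** 2, rtol=1e-5)


def test_thomas_k_closed_form_value():
    k = thomas_theoretical_k(Thomas(0.49, 0.17, 1.84), np.array([0.0, 0.19]))
    assert k.values[1] == pytest.approx(0.6607, abs=2e-4)


def test_thomas_simulation_agrees_with_theory(w80):
    """Mean empirical K over simulations within 3 MC SE of the closed form."""
    spec = Thomas(0.49, 0.17, 1.84)
    r = np.array([0.0, 0.2, 0.5, 1.0])
    vals = []
    for i in range(200):
        pat = simulate_model(spec, w80, seed=i)
        if pat.n >= 2:
            vals.append(k_translation(pat, r).values)
    vals = np.asarray(vals)
    mean = vals.mean(axis=0)
    se = vals.std(axis=0, ddof=1) / np.sqrt(len(vals))
    theo = thomas_theoretical_k(spec, r).values
    for k in range(1, len(r)):
        assert abs(mean[k] - theo[k]) < 3 * se[k]


# --------------------------------------------------------------------------- #
# Poisson fits

def test_fit_hom_poisson(csr_pattern):
    fit = fit_hom_poisson(csr_pattern)
    assert isinstance(fit.spec, HomPoisson)
    assert fit.spec.intensity == pytest.approx(csr_pattern.intensity)
    assert fit.converged


def test_fit_inhom_null_recovery(square10):
    pat = simulate_model(HomPoisson(1.0), square10, seed=11)
    fit = fit_inhom_poisson(pat)
    assert abs(fit.spec.beta1) < 3 * fit.stderr["beta1"]
    assert abs(fit.spec.beta2) < 3 * fit.stderr["beta2"]


def test_fit_inhom_integral_identity(square10):
    """∫_W λ̂ ≈ n (MLE score identity, quadrature-limited)."""
    pat = simulate_model(InhomPoisson(np.log(0.5), 0.2, 0.0), square10, seed=7)
    fit = fit_inhom_poisson(pat)
    # quadrature integral on a fine grid
    xs = np.linspace(0.05, 9.95, 100)
    ys = np.linspace(0.05, 9.95, 100)
    xx, yy = np.meshgrid(xs, ys)
    lam = fit.spec.intensity_at(xx, yy)
    integral = lam.sum() * 0.1 * 0.1
    assert integral == pytest.approx(pat.n, rel=0.01)


def test_fit_inhom_parameter_recovery(square10):
    """Median β̂1 over seeds within 3 SE of the true gradient 0.2."""
    b1, se = [], []
    for i in range(30):
        pat = simulate_model(InhomPoisson(np.log(0.5), 0.2, 0.0), square10,
                             seed=100 + i)
        fit = fit_inhom_poisson(pat)
        b1.append(fit.spec.beta1)
        se.append(fit.stderr["beta1"])
    assert abs(np.median(b1) - 0.2) < 3 * np.median(se)


def test_fit_inhom_requires_points(unit_square):
    with pytest.raises(ValueError):
        fit_inhom_poisson(PointPattern(unit_square, [[0.5, 0.5]]))


# --------------------------------------------------------------------------- #
# minimum-contrast fits

def test_thomas_fit_mu_identity(w80):
    pat = simulate_model(Thomas(0.49, 0.17, 1.84), w80, seed=42)
    fit = fit_thomas_mincontrast(pat)
    assert fit.spec.mu == pytest.approx(pat.intensity / fit.spec.kappa)


def test_thomas_mu_identity_printed_values():
    """λ̄/κ with the published rounded values: 0.91 / 0.49 ≈ 1.86 ≈ 1.84."""
    assert 0.91 / 0.49 == pytest.approx(1.86, abs=0.005)
    assert abs(0.91 / 0.49 - 1.84) < 0.03


def test_thomas_objective_ordering(w80):
    """True parameters beat (2κ, 2σ) for most large simulated patterns."""
    from bedplane.models import _contrast
    from bedplane.summaries import default_r_grid
    spec = Thomas(2.0, 0.17, 2.5)  # λ = 5, n ≈ 400
    r = default_r_grid(w80, 129)
    wins = 0
    n_trials = 20
    for i in range(n_trials):
        pat = simulate_model(spec, w80, seed=500 + i)
        k_obs = k_translation(pat, r).values
        def km(kappa, sigma):
            return (np.pi * r ** 2
                    + (1 - np.exp(-r ** 2 / (4 * sigma ** 2))) / kappa)
        d_true = _contrast(k_obs, km(2.0, 0.17), r)
        d_off = _contrast(k_obs, km(4.0, 0.34), r)
        wins += d_true < d_off
    assert wins > n_trials / 2


def test_thomas_fit_requires_n10(unit_square, rng):
    pat = PointPattern(unit_square, unit_square.uniform_points(5, rng))
    with pytest.raises(ValueError):
        fit_thomas_mincontrast(pat)


def test_gp_fit_deterministic(w80):
    pat = simulate_model(GaussPoissonPairs(0.52, 0.28, 0.75), w80, seed=9)
    f1 = fit_gauss_poisson_mincontrast(pat, m_sims=20, seed=33,
                                       r=np.linspace(0, 1.0, 33))
    f2 = fit_gauss_poisson_mincontrast(pat, m_sims=20, seed=33,
                                       r=np.linspace(0, 1.0, 33))
    assert f1.spec.radius == f2.spec.radius
    assert f1.spec.p_retain == f2.spec.p_retain
    assert f1.objective == f2.objective


def test_gp_fit_kappa_constraint(w80):
    pat = simulate_model(GaussPoissonPairs(0.52, 0.28, 0.75), w80, seed=9)
    fit = fit_gauss_poisson_mincontrast(pat, m_sims=20, seed=33,
                                        r=np.linspace(0, 1.0, 33))
    lam = pat.intensity
    assert fit.spec.kappa == pytest.approx(lam / (1 + fit.spec.p_retain))


def test_gp_fit_csr_input_weak_signal(square10):
    """A CSR pattern carries no pair signal: P̂ low or flagged."""
    pat = simulate_model(HomPoisson(1.0), square10, seed=4)
    fit = fit_gauss_poisson_mincontrast(pat, m_sims=30, seed=5,
                                        r=np.linspace(0, 1.25, 41))
    assert fit.boundary or fit.spec.p_retain < 0.5


def test_fitted_model_json_round_trip(tmp_path, csr_pattern):
    fit = fit_hom_poisson(csr_pattern)
    path = tmp_path / "fit.json"
    fit.save(path)
    import json
    loaded = json.loads(path.read_text())
    assert loaded["model"] == "HomPoisson"
    assert loaded["parameters"]["intensity"] == pytest.approx(1.0, abs=0.5)
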