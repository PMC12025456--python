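import numpy as np
import pytest

from fenestra.mechanics import IndenterModel
from fenestra.synthetic import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def sphere_model() -> IndenterModel:
    return IndenterModel(kind="sphere", tip_radius=25.0)


@pytest.fixture(scope="session")
def default_phantom():
    """Noisy 64x64 fenestrated-cell phantom (the standard study object)."""
    spec = PhantomSpec(seed=1)
    truth, fvmap = generate_phantom(spec)
    return spec, truth, fvmap


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = PhantomSpec(seed=2, force_noise_sd=0.0)
    truth, fvmap = generate_phantom(spec)
    return spec, truth, fvmap


@pytest.fixture(scope="session")
def flat_soft_phantom():
    """Bare soft-hydrogel phantom: no cell, 800 Pa substrate, long ramp."""
    spec = PhantomSpec(
        seed=3,
        grid_nx=8,
        grid_ny=8,
        cell_height=0.0,
        nucleus_height=0.0,
        nucleus_radius=0.0,
        n_sieve_plates=0,
        pores_per_plate=0,
        substrate_modulus=800.0,
        tip_radius=20.0,
        z_range=3000.0,
        force_noise_sd=0.0,
    )
    truth, fvmap = generate_phantom(spec)
    return spec, truth, fvmap


def hertz_curve(E=5000.0, z_c=300.0, R=25.0, nu=0.5, k=0.1, dmax=400.0, n=220):
    """Analytic noise-free sphere indentation curve (test helper)."""
    from fenestra.mechanics import ForceCurve, hertz_force_sphere

    delta = np.linspace(0.0, dmax, n)
    force = hertz_force_sphere(delta, E, nu, R)
    z_post = z_c + delta + force / (k * 1e3)
    z_pre = np.linspace(z_c - 280.0, z_c - 1.0, 120)
    return ForceCurve(
        z=np.concatenate([z_pre, z_post[1:]]),
        force=np.concatenate([np.zeros_like(z_pre), force[1:]]),
        spring_constant=k,
    )


def pyramid_curve(E=5000.0, z_c=300.0, half_angle=17.5, nu=0.5, k=0.1, dmax=400.0, n=220):
    from fenestra.mechanics import ForceCurve, sneddon_force_pyramid

    delta = np.linspace(0.0, dmax, n)
    force = sneddon_force_pyramid(delta, E, nu, half_angle)
    z_post = z_c + delta + force / (k * 1e3)
    z_pre = np.linspace(z_c - 280.0, z_c - 1.0, 120)
    return ForceCurve(
        z=np.concatenate([z_pre, z_post[1:]]),
        force=np.concatenate([np.zeros_like(z_pre), force[1:]]),
        spring_constant=k,
    )
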