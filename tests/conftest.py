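import numpy as np
import pytest

import carbopk as ck


@pytest.fixture(scope="session")
def constants():
    return ck.DosingConstants()


@pytest.fixture(scope="session")
def coeffs():
    return ck.load_coefficients()


@pytest.fixture(scope="session")
def pop_params():
    return ck.PKParameters()


@pytest.fixture(scope="session")
def event():
    return ck.DosingEvent(dose=600.0, infusion_duration=30.0)


@pytest.fixture
def reference_patient():
    """Covariates at the cystatin-C model's reference values (male)."""
    return ck.Patient(id="REF", sex="M", age=56, weight_kg=65.0, height_cm=170.0,
                      scr_umol_l=75.0, cysc_mg_l=1.0, target_auc=6.0)


@pytest.fixture
def golden_patient():
    """Fixed patient used for frozen hand-evaluated formula values."""
    return ck.Patient(id="G1", sex="F", age=62, weight_kg=85.0, height_cm=165.0,
                      scr_umol_l=88.0, cysc_mg_l=1.3, target_auc=5.0)


def random_patient(rng: np.random.Generator, **overrides) -> ck.Patient:
    """A random but valid patient; overrides pin individual fields."""
    fields = dict(
        id=f"R{rng.integers(1e6)}",
        sex="M" if rng.random() < 0.5 else "F",
        age=int(rng.integers(18, 90)),
        weight_kg=float(rng.uniform(45, 130)),
        height_cm=float(rng.uniform(150, 200)),
        scr_umol_l=float(rng.uniform(40, 150)),
        cysc_mg_l=float(rng.uniform(0.6, 2.0)),
        target_auc=float(rng.choice([4.0, 5.0, 6.0])),
    )
    fields.update(overrides)
    return ck.Patient(**fields)
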