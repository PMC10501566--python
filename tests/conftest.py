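import numpy as np
import pytest

from skitakeoff.model import JointDef, ModelDef, Muscle, Segment, load_model, toy_model_path
from skitakeoff.synthetic import SyntheticScenario, generate_aero_db, generate_takeoff_motion
from skitakeoff.tree import CompiledModel


@pytest.fixture(scope="session")
def toy_model():
    return load_model(toy_model_path("toy9"))


@pytest.fixture(scope="session")
def planar_model():
    return load_model(toy_model_path("planar4"))


def make_pendulum(m=2.0, l=0.5):
    """Anchor attached to ground by the free base, rod on a z-pin."""
    return ModelDef(
        segments=[
            Segment("anchor", mass=1.0, com_offset=np.zeros(3),
                    inertia=1e-3 * np.eye(3)),
            Segment("rod", mass=m, com_offset=np.array([0.0, -l, 0.0]),
                    inertia=np.diag([1e-4, 1e-5, 1e-4])),
        ],
        joints=[
            JointDef("base", "ground", "anchor", "free6dof"),
            JointDef("pin", "anchor", "rod", "pin",
                     axis=np.array([0.0, 0.0, 1.0])),
        ],
        name="pendulum",
    )


@pytest.fixture()
def pendulum():
    return make_pendulum()


@pytest.fixture(scope="session")
def takeoff():
    """The bundled noise-free synthetic squat-extension trial (seed 0)."""
    return generate_takeoff_motion(SyntheticScenario(seed=0))


@pytest.fixture(scope="session")
def static_trial():
    return generate_takeoff_motion(SyntheticScenario(seed=0, static=True))


@pytest.fixture(scope="session")
def aero_db():
    return generate_aero_db()


AFFINE_W = np.array(
    [[0.3, -0.1, 0.05, 0.02, -0.04, 0.01, 0.08],
     [-0.05, 0.2, -0.02, 0.03, 0.01, -0.06, 0.04],
     [0.01, 0.02, 0.03, -0.01, 0.02, 0.005, -0.03]]
)


def affine_force(p):
    """An affine function of the seven posture angles (multilinear-exact)."""
    x = np.array([p.delta1, p.delta2, p.delta3, p.delta4,
                  p.theta1, p.theta2, p.alpha])
    return np.array([10.0, -5.0, 2.0]) + AFFINE_W @ x


@pytest.fixture(scope="session")
def aero_db_affine():
    return generate_aero_db(coefficient_function=affine_force)


@pytest.fixture()
def compiled_toy(toy_model):
    return CompiledModel(toy_model)
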