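import numpy as np
import pytest

from skelref.reference import BoneReferenceTable, ClassReference
from skelref.skeleton import (
    KINECT21,
    NUITRACK20,
    FramePose,
    JointObservation,
    SkeletonDialect,
    TrackingState,
)


@pytest.fixture(scope="session")
def kinect():
    return KINECT21


@pytest.fixture(scope="session")
def nuitrack():
    return NUITRACK20


@pytest.fixture(scope="session")
def chain2():
    return SkeletonDialect("chain2", ("A", "B"), (("A", "B"),))


@pytest.fixture(scope="session")
def chain3():
    return SkeletonDialect("chain3", ("A", "B", "C"), (("A", "B"), ("B", "C")))


@pytest.fixture(scope="session")
def vee():
    """Two mirrored bones sharing a root: one symmetry pair."""
    return SkeletonDialect(
        "vee",
        ("RootJoint", "TipLeft", "TipRight"),
        (("RootJoint", "TipLeft"), ("RootJoint", "TipRight")),
        symmetry_pairs=((("RootJoint", "TipLeft"), ("RootJoint", "TipRight")),),
    )


def make_frame(t, positions, states=None):
    """Build a FramePose from a {joint: xyz} mapping."""
    states = states or {}
    return FramePose(
        timestamp=t,
        joints={
            name: JointObservation(
                position=np.asarray(p, dtype=float),
                state=states.get(name, TrackingState.TRACKED),
            )
            for name, p in positions.items()
        },
    )


@pytest.fixture
def frame_factory():
    return make_frame


def chain2_refs(l_ref=1.0):
    return BoneReferenceTable(
        classes={"A-B": ClassReference(l_ref_initial=l_ref, l_ref_final=l_ref)}
    )


@pytest.fixture
def chain2_table():
    return chain2_refs
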