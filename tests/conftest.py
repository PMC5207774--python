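import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crossbeta.interface import RadiusTable
from crossbeta.model_io import AtomSite
from crossbeta.synthetic import SheetSpec, ZipperSpec, build_sheet, build_zipper

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: hIAPP spine segments: 19–29 with the early-onset S20G substitution, and
#: wild-type 15–25 (residue numbering follows the full-length hormone).
SEQ_19_29_S20G = "SGNNFGAILSS"
SEQ_15_25_WT = "FLVHSSNNFGA"

#: Enlarged Cβ used with backbone+Cβ synthetic models to emulate side-chain
#: bulk at zipper interfaces.
SYNTH_RADII = RadiusTable(cb_radius=3.5)


@pytest.fixture(scope="session")
def flat_parallel_sheet():
    return build_sheet(SheetSpec(SEQ_19_29_S20G, n_strands=5))


@pytest.fixture(scope="session")
def antiparallel_shift2_sheet():
    return build_sheet(SheetSpec(
        SEQ_15_25_WT, n_strands=6, orientation="antiparallel",
        registry_shift=2, pleat_out_of_plane=True, residue_start=15))


@pytest.fixture(scope="session")
def class1_zipper():
    return build_zipper(ZipperSpec(
        sheet_a=SheetSpec(SEQ_19_29_S20G, n_strands=7),
        zipper_class=1, intersheet_distance=8.0, lateral_offset=2.4))


def carbon(serial, x, y, z, chain="A", resnum=1, name="C"):
    return AtomSite(serial, name, "C", "ALA", resnum, chain,
                    np.array([x, y, z], float))
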