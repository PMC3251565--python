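import pytest

from spindyn import DiffusionModel, ResidueRelaxationRecord, SpectrometerContext

TM_S = 6.38e-9

#: Published 600-MHz relaxation triplets (R1, err, R2, err, NOE, err)
#: for the RGD-loop residues of the wild-type and P48A proteins.
TABLE4 = {
    "A48_P48A": (48, 1.68, 0.07, 7.65, 0.13, 0.64, 0.01),
    "R49_WT": (49, 1.69, 0.08, 8.32, 0.13, 0.48, 0.01),
    "R49_P48A": (49, 1.63, 0.04, 5.98, 0.01, 0.42, 0.01),
    "G50_WT": (50, 1.55, 0.02, 5.09, 0.03, 0.32, 0.02),
    "G50_P48A": (50, 1.51, 0.02, 4.90, 0.01, 0.28, 0.01),
    "D51_WT": (51, 1.72, 0.03, 10.03, 0.02, 0.50, 0.02),
    "D51_P48A": (51, 1.68, 0.02, 6.50, 0.02, 0.47, 0.02),
}

#: Published model-free parameters (S2, te_ns, rex) for the same rows.
TABLE4_PARAMS = {
    "A48_P48A": (0.74, 1.04, 0.0),
    "R49_WT": (0.75, 0.11, 0.91),
    "R49_P48A": (0.53, 1.04, 0.0),
    "G50_WT": (0.50, 0.84, 0.0),
    "G50_P48A": (0.43, 0.93, 0.0),
    "D51_WT": (0.85, 0.19, 1.42),
    "D51_P48A": (0.61, 0.98, 0.0),
}


@pytest.fixture(scope="session")
def context600() -> SpectrometerContext:
    return SpectrometerContext()


@pytest.fixture(scope="session")
def diffusion() -> DiffusionModel:
    return DiffusionModel(kind="isotropic", tm_s=TM_S)


def record_for(key: str, context: SpectrometerContext) -> ResidueRelaxationRecord:
    rid, r1, e1, r2, e2, noe, en = TABLE4[key]
    return ResidueRelaxationRecord(
        residue_id=rid, r1=r1, r1_err=e1, r2=r2, r2_err=e2,
        noe=noe, noe_err=en, context=context,
    )


@pytest.fixture(scope="session")
def table4_records(context600):
    return {key: record_for(key, context600) for key in TABLE4}
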