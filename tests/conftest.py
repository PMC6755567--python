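import pandas as pd
import pytest

from shiftkit import embed_3d
from shiftkit.pipeline import RunManifest

METHANOL_INCHI = "InChI=1S/CH4O/c1-2/h2H,1H3"
METHYL_ISOTHIOCYANATE_INCHI = "InChI=1S/C2H3NS/c1-3-2-4/h1H3"
NITROMETHANE_INCHI = "InChI=1S/CH3NO2/c1-2(3)4/h1H3"
TUTORIAL_TRIO = [
    METHANOL_INCHI,
    METHYL_ISOTHIOCYANATE_INCHI,
    NITROMETHANE_INCHI,
]

FUNCTIONALS = ["BLYP", "B3LYP", "B35LYP", "BHLYP"]
BASES = ["cc-pVDZ", "cc-pVTZ"]


@pytest.fixture(scope="session")
def methanol():
    return embed_3d(METHANOL_INCHI)


@pytest.fixture(scope="session")
def tms():
    return embed_3d("InChI=1S/C4H12Si/c1-5(2,3)4/h1-4H3")


def write_trio_inputs(directory):
    """Write the tutorial molecule list and the 4x2 method matrix."""
    molecules = directory / "molecules.csv"
    molecules.write_text("\n".join(TUTORIAL_TRIO) + "\n")
    methods = directory / "methods.csv"
    pd.DataFrame(
        [
            {
                "functional": f,
                "basis": b,
                "solvent": "chloroform",
                "tasks": "shielding",
                "nuclei": "H C",
            }
            for f in FUNCTIONALS
            for b in BASES
        ]
    ).to_csv(methods, index=False)
    return molecules, methods


@pytest.fixture()
def trio_manifest(tmp_path):
    molecules, methods = write_trio_inputs(tmp_path)
    return RunManifest(
        molecules=molecules, methods=methods, outdir=tmp_path / "out"
    )
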