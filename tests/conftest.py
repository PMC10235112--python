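import pytest

from ppiiafp import SimParams


#: Fully sequenced tandem-MS tryptic fragments with their printed
#: monoisotopic [M+H]+ values (bracketed b-ion-inferred residues included).
TABLE1_VERIFIED_ROWS = {
    "GADGAAGGGFPGGK": 1118.5,
    "GGVGAPGGK": 699.4,
    "GAGGYGGAGGAGGAAGTK": 1336.6,
    "GAGGYGGAGGAGGAAGTKPA": 1504.7,
    "AGTAGTHGGFGGAGGAGGVG": 1515.7,
    "AGAANTNGNGGIGGAGGAGGACGTK": 1960.9,
    "CANGQSGGAGGTGGAGSAGGTCAGK": 1953.8,
    "CTDGANGANGADGAAGGGFPGGK": 1921.8,
    "GADGPVGASSGAHK": 1210.6,
    "SNGIVGNAGGTGCNGGVGK": 1618.8,
    "PAGIGAAGGNGGNAGTGGAGGYGGK": 1945.9,
    "GAGGYGGAGGAGGAAGTKPAGIGAAGGNGGNAGTGGAGGYGGK": 3263.5,
}

#: The missed-cleavage parent whose Lys-Pro bond breaks in-source.
KP_PARENT = "GAGGYGGAGGAGGAAGTKPAGIGAAGGNGGNAGTGGAGGYGGK"


@pytest.fixture
def noise_free_params():
    return SimParams(mass_noise_sd=0.0)
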