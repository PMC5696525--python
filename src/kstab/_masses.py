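"""Amino-acid residue mass constants.

Values are the standard residue (i.e. dehydrated) masses used by the common
protein-mass calculators (ExPASy-style tables), in daltons, to four decimals
for the average masses. A peptide mass is the sum of its residue masses plus
one water.
"""

#: Average residue masses (Da).
AVERAGE: dict[str, float] = {
    "G": 57.0519,
    "A": 71.0788,
    "S": 87.0782,
    "P": 97.1167,
    "V": 99.1326,
    "T": 101.1051,
    "C": 103.1388,
    "L": 113.1594,
    "I": 113.1594,
    "N": 114.1038,
    "D": 115.0886,
    "Q": 128.1307,
    "K": 128.1741,
    "E": 129.1155,
    "M": 131.1926,
    "H": 137.1411,
    "F": 147.1766,
    "R": 156.1875,
    "Y": 163.1760,
    "W": 186.2132,
}

#: Monoisotopic residue masses (Da).
MONOISOTOPIC: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

#: Mass of one water molecule (Da), added once per peptide chain.
WATER_AVERAGE: float = 18.0153
WATER_MONOISOTOPIC: float = 18.010565
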