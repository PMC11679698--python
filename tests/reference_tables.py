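"""Published varimax-rotated loading tables from a co-located strawberry-leaf /
lichen biomonitoring survey, used as audit inputs for the PCA bookkeeping
accessors (communalities, per-component and total explained variance)."""

import pandas as pd

LEAF_LOADINGS = pd.DataFrame(
    {
        "PC1": [0.85, 0.83, 0.78, 0.645, 0.096, 0.205, 0.024, 0.029, 0.141,
                0.583, -0.125, -0.098, 0.039],
        "PC2": [0.006, 0.289, 0.118, 0.07, 0.941, 0.889, 0.5, 0.22, 0.215,
                -0.2, 0.243, -0.251, 0.413],
        "PC3": [0.172, 0.067, -0.296, 0.319, 0.106, 0.048, 0.249, 0.853,
                0.778, 0.584, 0.235, -0.366, -0.25],
        "PC4": [-0.106, -0.058, -0.1, 0.028, 0.028, 0.203, 0.034, -0.084,
                -0.15, 0.096, 0.831, 0.725, 0.665],
    },
    index=["K", "Al", "Si", "Cl", "Cr", "Fe", "Mn", "P", "S", "Mg", "Zn",
           "Pb", "Ti"],
)
LEAF_EXPLAINED_PCT = [29.2, 18.8, 14.3, 9.4]
LEAF_REPORTED_COMMUNALITY = {"Zn": 0.82}

LICHEN_LOADINGS = pd.DataFrame(
    {
        "PC1": [0.965, 0.96, 0.856, 0.74, 0.277, 0.347, 0.259, -0.422, 0.236,
                0.474, -0.034],
        "PC2": [0.088, 0.068, 0.437, 0.327, 0.902, 0.871, 0.817, 0.658,
                0.307, 0.044, -0.124],
        "PC3": [0.145, 0.185, 0.154, 0.077, 0.005, -0.026, 0.027, 0.12,
                0.734, 0.606, 0.579],
    },
    index=["Mn", "Cr", "Fe", "Mg", "Si", "Al", "Ti", "K", "S", "Zn", "Pb"],
)
LICHEN_EXPLAINED_PCT = [46.5, 19.3, 9.6]
LICHEN_REPORTED_COMMUNALITY = {"Mn": 0.96}
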