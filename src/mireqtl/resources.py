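"""Packaged reference tables.

``reference_model_coefficients.tsv`` transcribes the reported miR-eQTL
prognostic model for MCI-to-AD conversion: the three clinical factors (age,
sex, APOE4 allele count) and the 24 SNP-miRNA pairs retained at adjusted
permutation P < 0.1, with their Cox coefficients.
"""

from __future__ import annotations

from importlib import resources as _res

import pandas as pd


def load_reference_model() -> tuple[pd.Series, pd.DataFrame]:
    """Return ``(clinical_coefficients, pair_table)``.

    The clinical coefficients are a Series (age, sex, apoe4 -> log-hazard
    ratio); the pair table has columns ``mirna``, ``snp``, ``p_adjusted``,
    ``coefficient``.
    """
    path = _res.files("mireqtl").joinpath("data/reference_model_coefficients.tsv")
    with _res.as_file(path) as p:
        table = pd.read_csv(p, sep="\t", na_values=["NA"])
    clinical = (
        table[table["factor_type"] == "clinical"]
        .set_index("mirna")["coefficient"]
    )
    clinical.index.name = "factor"
    pairs = table[table["factor_type"] == "pair"].drop(columns="factor_type")
    return clinical, pairs.reset_index(drop=True)
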