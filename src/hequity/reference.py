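"""Published country-level index estimates for worked examples and checks.

The bundled table holds the Erreygers-corrected concentration index (robust
SE) and the horizontal inequity index (bootstrap SE) of postponed and denied
care for 25 European countries during the first COVID-19 wave, as published
from the SHARE COVID-19 module, together with their printed significance
stars (* p<0.1, ** p<0.05, *** p<0.01). The estimate/SE pairs serve as
inputs to the significance-flagging machinery — e.g. re-deriving which
countries show significant inequity at a given level.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_published_indices() -> pd.DataFrame:
    """Long-format table: country, outcome (postponed/denied), measure
    (cci/hi), estimate, se, stars (missing stars read as empty strings)."""
    with resources.files("hequity").joinpath("data/published_indices.csv").open() as f:
        df = pd.read_csv(f, keep_default_na=False)
    return df
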