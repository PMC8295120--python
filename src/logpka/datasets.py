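"""Shipped reference datasets: the SAMPL7 N-acylsulfonamide benchmark.

Two small CSV tables pair the IEFPCM/MST blind-challenge predictions for the
22 SAMPL7 compounds (SM25–SM46) with the experimental references:

* ``load_sampl7_logp()`` — n-octanol/water log P, 22 compounds.
* ``load_sampl7_pka()``  — macroscopic pKa.  SM28 and SM33 have censored
  experimental values ("> 12.00") and are auto-excluded from statistics;
  SM25 carries the originally submitted value 7.24 (a post-submission
  revision found a conformer-weighting mistake; the corrected value 3.30
  rides along as an annotation, not in the statistics path).

The canonical matched methyl → phenyl substituent pairs of this series are
exposed as :data:`METHYL_PHENYL_PAIRS`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .evaluation import PredictionRecord

__all__ = [
    "METHYL_PHENYL_PAIRS",
    "load_sampl7_logp",
    "load_sampl7_pka",
]

#: (methyl compound, phenyl compound) pairs differing by a methyl → phenyl
#: replacement; SM35/SM36 is kept separate as the series' known exception.
METHYL_PHENYL_PAIRS: tuple[tuple[str, str], ...] = (
    ("SM41", "SM42"),
    ("SM29", "SM30"),
    ("SM32", "SM33"),
    ("SM38", "SM39"),
    ("SM44", "SM45"),
)


def _read_fixture(name: str) -> pd.DataFrame:
    with resources.files("logpka.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, dtype={"compound_id": str})


def load_sampl7_logp() -> list[PredictionRecord]:
    """Calculated vs experimental log P for the 22 SAMPL7 compounds."""
    df = _read_fixture("table1_logp.csv")
    return [
        PredictionRecord.from_raw(row.compound_id, row.calculated, row.experimental)
        for row in df.itertuples()
    ]


def load_sampl7_pka() -> list[PredictionRecord]:
    """Calculated vs experimental macroscopic pKa for the SAMPL7 compounds.

    Censored experimental bounds are parsed and auto-excluded; the revised
    SM25 value is attached as an annotation.
    """
    df = _read_fixture("table2_pka.csv")
    records = []
    for row in df.itertuples():
        annotation = None
        if pd.notna(row.calculated_corrected):
            annotation = f"corrected calculated value {row.calculated_corrected:.2f}"
        records.append(
            PredictionRecord.from_raw(
                row.compound_id, row.calculated, row.experimental, annotation=annotation
            )
        )
    return records
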