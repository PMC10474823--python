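"""Published reference summary statistics bundled for consistency checks.

A validation study of the folded-wing method measured three intraspecific
specimen series with both the spread-wing image method and the folded-wing
closed forms: *Archilochus colubris* (Ruby-throated Hummingbird, n = 17,
elongated pointy wings), *Columba livia* (Rock Dove, n = 18, intermediate
wings) and *Cyanocitta cristata* (Blue Jay, n = 16, short rounded wings).
For each series the published table reports, per method/model, the mean
total wing area (cm^2), its sample standard deviation, the coefficient of
variation (%), and the folded-wing mean's percent difference from the
spread-wing mean.

Only the printed summary numbers are bundled here (the underlying
specimen-level measurements are not); they serve as reference inputs for
internal-consistency checks — recomputing CV as 100*SD/mean and percent
difference as the ratio of means must round back to the printed values.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["intraspecific_reference", "interspecific_reference"]

_INTRASPECIFIC_ROWS = [
    # species, method/model, n, mean cm^2, printed % difference, SD, printed CV %
    ("Archilochus colubris", "spread", 17, 13.5, None, 1.47, 10.9),
    ("Archilochus colubris", "triangle", 17, 11.0, -19.1, 1.08, 9.8),
    ("Archilochus colubris", "ellipse", 17, 14.9, 9.8, 1.38, 9.3),
    ("Archilochus colubris", "ellipse-triangle", 17, 13.6, 0.2, 1.28, 9.4),
    ("Columba livia", "spread", 18, 661.0, None, 42.8, 6.5),
    ("Columba livia", "triangle", 18, 536.3, -18.9, 27.3, 5.1),
    ("Columba livia", "ellipse", 18, 689.4, 4.3, 33.9, 4.9),
    ("Columba livia", "ellipse-triangle", 18, 638.4, -3.4, 31.5, 4.9),
    ("Cyanocitta cristata", "spread", 16, 365.8, None, 20.7, 5.7),
    ("Cyanocitta cristata", "triangle", 16, 305.6, -16.5, 13.0, 4.3),
    ("Cyanocitta cristata", "ellipse", 16, 386.1, 5.6, 15.4, 4.0),
    ("Cyanocitta cristata", "ellipse-triangle", 16, 359.3, -1.8, 14.6, 4.1),
]

_INTERSPECIFIC_ROWS = [
    # quantity, model, published discrepancy, slope, SE, r2, lambda (59 species)
    ("area", "triangle", -4.5, 1.26, 0.011, 0.995, 1.0),
    ("area", "ellipse", 1.5, 1.04, 0.010, 0.992, 1.0),
    ("area", "ellipse-triangle", -0.4, 1.10, 0.004, 0.993, 1.0),
    ("aspect_ratio", "triangle", 4.5, 0.82, 0.021, 0.920, 1.0),
    ("aspect_ratio", "ellipse", -1.5, 1.03, 0.029, 0.909, 1.0),
    ("aspect_ratio", "ellipse-triangle", 0.4, 0.97, 0.025, 0.919, 1.0),
]


def intraspecific_reference() -> pd.DataFrame:
    """Published intraspecific accuracy/precision summaries (three species)."""
    return pd.DataFrame(
        _INTRASPECIFIC_ROWS,
        columns=["species", "method", "n", "mean", "pct_diff", "sd", "cv"],
    )


def interspecific_reference() -> pd.DataFrame:
    """Published interspecific discrepancy and through-origin PGLS summaries."""
    return pd.DataFrame(
        _INTERSPECIFIC_ROWS,
        columns=["quantity", "method", "discrepancy", "slope", "se", "r2", "lambda"],
    )
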