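"""Published reference values usable as worked-example inputs.

``RSEPI_SI_TABLE`` holds the per-lesion mean b1000 signal intensities
(lesion ROI and pooled GM background) printed for the rs-EPI series of the
source phantom study, from which the relative-contrast column of its results
table is recomputable.  These are inputs to worked examples and fixtures,
not values the simulator is fitted to.
"""

from __future__ import annotations

import pandas as pd

# lesion diameter (mm) -> (mean SI_ROI, mean SI_GM) on b1000 rs-EPI images
RSEPI_SI_TABLE = {
    10.0: (676.31, 597.80),
    7.0: (686.63, 602.58),
    5.0: (692.65, 601.12),
    4.0: (687.77, 598.00),
    3.0: (682.02, 593.82),
}


def rsepi_si_frame() -> pd.DataFrame:
    """The reference SI table as a tidy DataFrame."""
    rows = [dict(lesion_mm=d, si_roi=roi, si_gm=gm)
            for d, (roi, gm) in sorted(RSEPI_SI_TABLE.items(), reverse=True)]
    return pd.DataFrame(rows)
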