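#!/usr/bin/env python
"""Inter-rater agreement on the reconstructed two-rater Likert tables.

Weighted kappa (linear weights) with asymptotic 95% CI, the Altman
interpretation band, and raw percent agreement, per rating criterion.
Output: results/ratings/rater_agreement.csv.
"""

from pathlib import Path

import pandas as pd

from dwiphantom.ratings import CRITERIA, rating_vectors, reference_rating_table
from dwiphantom.stats import percent_agreement, weighted_kappa

OUT = Path("results/ratings")


def main() -> None:
    table = reference_rating_table()
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "ratings.csv", index=False)

    rows = []
    for criterion in CRITERIA:
        r1, r2 = rating_vectors(table, criterion)
        k = weighted_kappa(r1, r2)
        pct, _ = percent_agreement(r1, r2)
        rows.append(dict(
            criterion=criterion,
            kappa=None if k.degenerate else round(k.kappa, 2),
            ci_low=None if k.degenerate else round(k.ci95[0], 2),
            ci_high=None if k.degenerate else round(k.ci95[1], 2),
            altman=k.altman if not k.degenerate else "undefined",
            percent_agreement=pct,
        ))
    result = pd.DataFrame(rows)
    result.to_csv(OUT / "rater_agreement.csv", index=False)
    print(result.to_string(index=False))


if __name__ == "__main__":
    main()
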