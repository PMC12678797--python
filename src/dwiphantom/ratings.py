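"""Likert rating data model and the reference two-rater rating tables.

Two raters score n images (five per sequence, three sequences) on six
criteria using a 0-4 Likert scale.  The tidy representation is a DataFrame
with columns ``rater, image_id, sequence, criterion, score``.

``reference_rating_table`` reconstructs the published per-rater score
distributions of the source study from its per-sequence means/SDs and
per-image counts.  Within a sequence the assignment of scores to individual
images is not recorded anywhere, so scores are laid out deterministically
(lower scores on the earlier images); the table is a synthetic
reconstruction, exact in distribution per rater x sequence x criterion but
arbitrary in within-sequence order.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

CRITERIA = ("contrast", "susceptibility", "distortion", "noise", "resolution", "overall")
SEQUENCES = ("ssEPI", "rsEPI", "TGSE_BLADE")
N_PER_SEQUENCE = 5

# per (criterion, rater, sequence): multiset of five scores.
# Distribution-exact reconstruction of the published ratings; contrast follows
# the prose account exactly (rater 2 marked one ss-EPI image one step lower).
_SCORES = {
    "contrast": {
        1: {"ssEPI": [3, 3, 3, 3, 3], "rsEPI": [3, 3, 3, 3, 3], "TGSE_BLADE": [3, 3, 3, 3, 3]},
        2: {"ssEPI": [2, 3, 3, 3, 3], "rsEPI": [3, 3, 3, 3, 3], "TGSE_BLADE": [3, 3, 3, 3, 3]},
    },
    "susceptibility": {
        1: {"ssEPI": [2, 2, 2, 2, 2], "rsEPI": [2, 2, 2, 3, 3], "TGSE_BLADE": [3, 3, 3, 3, 4]},
        2: {"ssEPI": [2, 2, 2, 2, 2], "rsEPI": [3, 3, 3, 3, 3], "TGSE_BLADE": [3, 3, 3, 3, 3]},
    },
    "distortion": {
        1: {"ssEPI": [1, 1, 2, 2, 2], "rsEPI": [2, 2, 3, 3, 3], "TGSE_BLADE": [3, 3, 3, 3, 4]},
        2: {"ssEPI": [2, 2, 2, 2, 3], "rsEPI": [3, 3, 3, 3, 3], "TGSE_BLADE": [3, 3, 3, 3, 3]},
    },
    "noise": {
        1: {"ssEPI": [2, 2, 2, 2, 3], "rsEPI": [2, 2, 3, 3, 3], "TGSE_BLADE": [3, 3, 3, 3, 3]},
        2: {"ssEPI": [2, 2, 2, 3, 3], "rsEPI": [3, 3, 3, 3, 3], "TGSE_BLADE": [2, 3, 3, 3, 3]},
    },
    "resolution": {
        1: {"ssEPI": [2, 3, 3, 3, 3], "rsEPI": [3, 3, 3, 3, 3], "TGSE_BLADE": [3, 3, 3, 3, 3]},
        2: {"ssEPI": [2, 2, 3, 3, 3], "rsEPI": [3, 3, 3, 3, 3], "TGSE_BLADE": [2, 2, 3, 3, 3]},
    },
    "overall": {
        1: {"ssEPI": [2, 2, 2, 3, 3], "rsEPI": [2, 3, 3, 3, 3], "TGSE_BLADE": [3, 3, 3, 3, 3]},
        2: {"ssEPI": [2, 2, 2, 2, 3], "rsEPI": [3, 3, 3, 3, 3], "TGSE_BLADE": [2, 3, 3, 3, 3]},
    },
}


def reference_rating_table(criteria: Sequence[str] = CRITERIA) -> pd.DataFrame:
    """Tidy reconstruction of the two-rater study ratings (see module docstring)."""
    rows = []
    for criterion in criteria:
        if criterion not in _SCORES:
            raise KeyError(f"unknown criterion {criterion!r}")
        for rater, by_seq in _SCORES[criterion].items():
            for seq in SEQUENCES:
                for i, score in enumerate(by_seq[seq]):
                    rows.append(dict(rater=rater, image_id=f"{seq}_{i + 1}",
                                     sequence=seq, criterion=criterion, score=score))
    return pd.DataFrame(rows)


def rating_vectors(table: pd.DataFrame, criterion: str) -> tuple[list[int], list[int]]:
    """Aligned per-image score vectors (rater 1, rater 2) for one criterion."""
    sub = table[table["criterion"] == criterion]
    if sub.empty:
        raise KeyError(f"criterion {criterion!r} not in table")
    pivot = sub.pivot_table(index="image_id", columns="rater", values="score")
    if pivot.isna().any().any():
        raise ValueError("both raters must score every image")
    return pivot[1].astype(int).tolist(), pivot[2].astype(int).tolist()


def load_ratings_csv(path) -> pd.DataFrame:
    """Read a tidy ratings CSV (rater, image_id, sequence, criterion, score)."""
    table = pd.read_csv(path)
    required = {"rater", "image_id", "sequence", "criterion", "score"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ratings CSV missing columns: {sorted(missing)}")
    if not table["score"].isin(range(5)).all():
        raise ValueError("scores must be integers 0-4")
    return table
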