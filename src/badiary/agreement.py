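"""Inter-rater agreement for transcribed activity categories.

Diary transcription assigns categories by hand; with two independent
raters, chance-corrected agreement is summarized by Cohen's kappa
computed from the raters' confusion matrix.
"""

from __future__ import annotations

import warnings
from collections import Counter
from typing import Hashable, Sequence

__all__ = ["cohens_kappa"]


def cohens_kappa(
    labels_a: Sequence[Hashable], labels_b: Sequence[Hashable]
) -> float:
    """Cohen's kappa between two raters' label sequences.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with ``p_o`` the observed agreement
    fraction and ``p_e`` the chance agreement implied by the two raters'
    marginal label frequencies.

    When both raters are constant and identical, ``p_e = 1`` and the ratio
    is undefined; kappa is then defined as 1 with a degenerate-marginals
    warning (agreement is perfect, chance correction is vacuous).

    Raises
    ------
    ValueError
        On length mismatch or fewer than 2 items.
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError(f"label sequences differ in length: {len(a)} vs {len(b)}")
    n = len(a)
    if n < 2:
        raise ValueError("kappa requires at least 2 rated items")

    p_o = sum(x == y for x, y in zip(a, b)) / n
    marg_a = Counter(a)
    marg_b = Counter(b)
    p_e = sum(marg_a[lab] * marg_b.get(lab, 0) for lab in marg_a) / (n * n)
    if p_e >= 1.0:
        warnings.warn(
            "both raters constant and identical: chance agreement is 1, "
            "kappa defined as 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)
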