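"""Pairwise Sørensen dissimilarities between compounds from shared features.

For compounds X and Y with ``a`` shared features, ``b`` features unique to X
and ``c`` unique to Y, the Sørensen (Dice) dissimilarity is

    d = 1 - 2a / (2a + b + c).

Small values mean the two compounds are made by largely the same enzymes;
d = 0 marks biosynthetically identical compounds (multi-product enzymes,
e.g. a terpene synthase releasing both α- and β-pinene), d = 1 compounds
with no enzyme in common (different pathways).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io_matrices import CompoundFeatureMatrix, DistanceMatrix

__all__ = ["sorensen_matrix"]


def sorensen_matrix(features: CompoundFeatureMatrix) -> DistanceMatrix:
    """Sørensen dissimilarity between every compound pair.

    Parameters
    ----------
    features
        Compound × feature 0/1 incidence; each compound must carry at least
        one feature (guaranteed by the type's validation).

    Returns
    -------
    DistanceMatrix
        Over ``features.compound_ids``, entries in [0, 1].
    """
    x = features.values.astype(bool)
    # scipy's "dice" metric is exactly 1 - 2a/(2a+b+c) on boolean vectors
    condensed = pdist(x, metric="dice")
    return DistanceMatrix(features.compound_ids, squareform(condensed))
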