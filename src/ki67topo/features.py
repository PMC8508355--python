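"""Full feature extractor: 490 named descriptors per cell pattern.

Fixed column order: graph features (441), stochastic-geometry features
(39), windowed-entropy features (6), fractality features (4).
"""
from __future__ import annotations

from collections import OrderedDict

import pandas as pd

from .datatypes import CellPattern
from .entropy import entropy_block, entropy_feature_names
from .fractal import FRACTAL_FEATURE_NAMES, fractal_block
from .graphfeat import graph_feature_block, graph_feature_names
from .pointprocess import pointprocess_feature_block, pointprocess_feature_names

BLOCK_SIZES = {"graph": 441, "pointprocess": 39, "entropy": 6, "fractal": 4}
TOTAL_FEATURES = sum(BLOCK_SIZES.values())


def feature_names() -> list[str]:
    """The 490 feature names in canonical order."""
    return (
        graph_feature_names()
        + pointprocess_feature_names()
        + entropy_feature_names()
        + FRACTAL_FEATURE_NAMES
    )


def extract_features(pattern: CellPattern) -> pd.Series:
    """Compute the full 490-feature vector for one pattern."""
    out: "OrderedDict[str, float]" = OrderedDict()
    out.update(graph_feature_block(pattern))
    out.update(pointprocess_feature_block(pattern))
    out.update(entropy_block(pattern))
    out.update(fractal_block(pattern))
    s = pd.Series(out, dtype=float)
    assert len(s) == TOTAL_FEATURES, f"expected {TOTAL_FEATURES} features, got {len(s)}"
    return s
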