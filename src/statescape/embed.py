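"""Morphospace embedding: 2-D visualization of scalar-measure vectors.

Each analyzed unit (a channel's OPN) is a point in a 5-D "dynamical
morphospace" whose axes are its scalar measures (node count, edge count,
determinism, degeneracy, modularity). A seeded nonlinear neighbour
embedding (UMAP) projects these to 2-D for visualization only: the
resulting axes carry no intrinsic meaning and no quantitative conclusion
is drawn from coordinates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler

__all__ = ["DEFAULT_FEATURES", "morphospace_embed"]

DEFAULT_FEATURES = ["n_nodes", "n_edges", "det", "deg", "modularity_q"]


def morphospace_embed(
    table: pd.DataFrame,
    features: list[str] | None = None,
    seed: int = 0,
    n_neighbors: int = 15,
) -> np.ndarray:
    """2-D seeded UMAP embedding of standardized measure vectors.

    Requires the ``embed`` extra (umap-learn). Returns an ``(n_rows, 2)``
    coordinate array aligned with the table's rows.
    """
    feats = features if features is not None else DEFAULT_FEATURES
    missing = [f for f in feats if f not in table.columns]
    if missing:
        raise ValueError(f"features missing from table: {missing}")
    x = table[feats].to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 rows to embed")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature matrix contains non-finite values")
    x = StandardScaler().fit_transform(x)
    try:
        import umap
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("morphospace embedding requires umap-learn; install statescape[embed]") from exc
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, x.shape[0] - 1),
        random_state=seed,
    )
    return np.asarray(reducer.fit_transform(x), dtype=float)
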