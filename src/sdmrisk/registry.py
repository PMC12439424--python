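"""The predictor registry: the 45 bioclimatic, topographic and soil layers.

The registry ships as a packaged CSV and supplies canonical layer names,
codes, units and source tags for synthetic stacks and reports.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd


@lru_cache(maxsize=1)
def load_registry() -> pd.DataFrame:
    """Registry table indexed by layer name (45 rows)."""
    with resources.files("sdmrisk.data").joinpath("predictor_registry.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("name")


def registry_names(n: int | None = None) -> list[str]:
    """First ``n`` canonical layer names (all 45 when n is None)."""
    names = list(load_registry().index)
    if n is None:
        return names
    if n <= len(names):
        return names[:n]
    # beyond the registry, fall back to generic names
    return names + [f"layer{i:02d}" for i in range(len(names), n)]


def registry_entry(name: str) -> dict:
    df = load_registry()
    if name in df.index:
        return df.loc[name].to_dict()
    return {"code": name, "description": name, "source": "synthetic", "units": "-"}
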