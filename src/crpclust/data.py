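"""Container and I/O for integer-coded multivariate categorical responses.

The dataset is an ``N x D`` matrix of integer codes, where dimension ``d``
has ``V_d >= 2`` response options coded ``0 .. V_d - 1``.  Missingness is not
supported: states such as "not applicable" are modeled as an extra category of
their own dimension.  An optional per-row categorical outcome label (e.g.
party identification) travels with the dataset but is never seen by the
sampler; it is used only for post-hoc cluster profiling.

On disk a dataset is a plain CSV (header = item labels, one coded row per
respondent, optional trailing outcome column) plus a JSON or YAML sidecar
schema listing the category count per item and the outcome column name.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml


@dataclass
class CategoricalDataset:
    responses: np.ndarray
    category_counts: np.ndarray
    item_labels: list[str] = field(default_factory=list)
    outcome: list[str] | None = None
    outcome_name: str = "outcome"

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=np.int64)
        self.category_counts = np.asarray(self.category_counts, dtype=np.int64)
        if self.responses.ndim != 2:
            raise ValueError("responses must be an N x D matrix")
        n, d = self.responses.shape
        if n < 1 or d < 1:
            raise ValueError("dataset must have N >= 1 rows and D >= 1 items")
        if self.category_counts.shape != (d,):
            raise ValueError("category_counts must have one entry per item")
        if np.any(self.category_counts < 2):
            raise ValueError("every dimension needs at least 2 categories")
        if np.any(self.responses < 0) or np.any(self.responses >= self.category_counts):
            raise ValueError("response codes out of range for their dimension")
        if not self.item_labels:
            self.item_labels = [f"item_{d_}" for d_ in range(d)]
        if len(self.item_labels) != d:
            raise ValueError("item_labels must have one entry per item")
        if self.outcome is not None and len(self.outcome) != n:
            raise ValueError("outcome must have one label per row")

    @property
    def n(self) -> int:
        return self.responses.shape[0]

    @property
    def d(self) -> int:
        return self.responses.shape[1]

    # -- I/O ------------------------------------------------------------------

    def to_csv(self, path: str | Path, schema_path: str | Path | None = None) -> None:
        """Write the coded matrix as CSV and the schema as a JSON/YAML sidecar."""
        path = Path(path)
        frame = pd.DataFrame(self.responses, columns=self.item_labels)
        if self.outcome is not None:
            frame[self.outcome_name] = self.outcome
        frame.to_csv(path, index=False)
        if schema_path is None:
            schema_path = path.with_suffix(".schema.json")
        schema = {
            "category_counts": {lbl: int(v) for lbl, v in zip(self.item_labels, self.category_counts)},
            "outcome_column": self.outcome_name if self.outcome is not None else None,
        }
        schema_path = Path(schema_path)
        if schema_path.suffix in {".yaml", ".yml"}:
            schema_path.write_text(yaml.safe_dump(schema, sort_keys=False))
        else:
            schema_path.write_text(json.dumps(schema, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path, schema_path: str | Path | None = None) -> "CategoricalDataset":
        path = Path(path)
        if schema_path is None:
            schema_path = path.with_suffix(".schema.json")
        schema_path = Path(schema_path)
        if schema_path.suffix in {".yaml", ".yml"}:
            schema = yaml.safe_load(schema_path.read_text())
        else:
            schema = json.loads(schema_path.read_text())
        frame = pd.read_csv(path)
        counts = schema["category_counts"]
        labels = list(counts.keys())
        outcome_col = schema.get("outcome_column")
        outcome = frame[outcome_col].astype(str).tolist() if outcome_col else None
        return cls(
            responses=frame[labels].to_numpy(),
            category_counts=np.array([counts[lbl] for lbl in labels]),
            item_labels=labels,
            outcome=outcome,
            outcome_name=outcome_col or "outcome",
        )


def validate_observation(obs: Sequence[int], category_counts: np.ndarray) -> np.ndarray:
    """Coerce and range-check a single length-D response vector."""
    obs = np.asarray(obs, dtype=np.int64)
    category_counts = np.asarray(category_counts, dtype=np.int64)
    if obs.shape != category_counts.shape:
        raise ValueError("observation length does not match number of dimensions")
    if np.any(obs < 0) or np.any(obs >= category_counts):
        raise ValueError("response code out of range for its dimension")
    return obs
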