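"""Classification task definitions over the corpus labels.

Three tasks share one corpus: pain vs. non-pain (all clips), cold vs. warm
(all clips), and graded pain intensity (pain clips only, three classes).
Class orders fix the integer encodings used everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TaskSpec", "TASKS", "select_task"]


@dataclass(frozen=True)
class TaskSpec:
    name: str
    label_column: str
    class_names: tuple[str, ...]
    pain_only: bool = False

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


TASKS: dict[str, TaskSpec] = {
    "pain_binary": TaskSpec("pain_binary", "pain", ("non-pain", "pain")),
    "thermal_binary": TaskSpec("thermal_binary", "thermal", ("cold", "warm")),
    "intensity_3class": TaskSpec(
        "intensity_3class", "intensity", ("mild", "moderate", "severe"), pain_only=True
    ),
}


def select_task(corpus: pd.DataFrame, spec: TaskSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Filter the corpus for a task and encode labels as integers.

    Returns the (possibly filtered) clip table and the aligned label
    vector.  The intensity task keeps only pain clips.  Raises if any task
    class ends up with no clips.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    subset = corpus[corpus["pain"] == "pain"] if spec.pain_only else corpus
    subset = subset.reset_index(drop=True)
    unknown = set(subset[spec.label_column]) - set(spec.class_names)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} not in task classes {spec.class_names}")
    encoder = {name: i for i, name in enumerate(spec.class_names)}
    labels = subset[spec.label_column].map(encoder).to_numpy(dtype=np.intp)
    present = np.bincount(labels, minlength=spec.n_classes)
    if np.any(present == 0):
        missing = [spec.class_names[i] for i in np.flatnonzero(present == 0)]
        raise ValueError(f"task {spec.name}: classes {missing} absent after filtering")
    return subset, labels
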