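"""Trial data model, condition-name parsing, file I/O and transient trimming.

A *trial* is one 2-s sweep of an optogenetically evoked local field
potential (LFP), sampled at 10 kHz.  Trials come in ensembles of 100 per
animal and pharmacological condition; the :class:`TrialSet` is the unit on
which every downstream analysis stage (alignment, clustering, embedding,
spectral modeling) operates.

Condition names follow the ``<antagonist><order><mouse>`` convention used
in the recordings, e.g. ``schb14`` = SCH 23390 applied *before* cocaine,
mouse 14; ``bc8`` = the baseline recording for mouse 8.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import h5py
import numpy as np

__all__ = [
    "Antagonist",
    "Order",
    "ConditionLabel",
    "Trial",
    "TrialSet",
    "parse_trial_name",
    "trim_transient",
    "read_trialset",
    "write_trialset",
    "concat_matrix",
    "TrialNameError",
]


class TrialNameError(ValueError):
    """Raised when a trial name does not follow the naming convention."""


class Antagonist(str, Enum):
    SCH = "sch"        # D1-like antagonist SCH 23390
    SULP = "sulp"      # D2-like antagonist sulpiride
    BOTH = "both"      # both antagonists together
    NONE = "none"      # no antagonist (baseline / cocaine-only recording)


class Order(str, Enum):
    BEFORE_COCAINE = "before_cocaine"
    AFTER_COCAINE = "after_cocaine"
    BASELINE = "baseline"
    COCAINE_ONLY = "cocaine_only"


@dataclass(frozen=True)
class ConditionLabel:
    """Pharmacological condition of a trial set."""

    antagonist: Antagonist = Antagonist.NONE
    order: Order = Order.BASELINE

    def __post_init__(self) -> None:
        no_drug = self.antagonist is Antagonist.NONE
        drug_free_order = self.order in (Order.BASELINE, Order.COCAINE_ONLY)
        if no_drug != drug_free_order:
            raise ValueError(
                f"inconsistent condition: antagonist={self.antagonist.value} "
                f"with order={self.order.value}"
            )

    @property
    def short(self) -> str:
        """Compact name stem, e.g. ``schb`` or ``bc``."""
        if self.antagonist is Antagonist.NONE:
            return "bc" if self.order is Order.BASELINE else "c"
        suffix = "b" if self.order is Order.BEFORE_COCAINE else "a"
        return f"{self.antagonist.value}{suffix}"


_NAME_RE = re.compile(r"^(sch|sulp|both|bc)([ab])?(\d+)$")


def parse_trial_name(name: str) -> tuple[ConditionLabel, int]:
    """Parse a trial-set name such as ``schb14`` or ``bc8``.

    Returns the structured condition label and the mouse number.  ``bc``
    names denote baseline recordings and carry no before/after letter.
    """
    m = _NAME_RE.match(name.strip())
    if m is None:
        raise TrialNameError(f"unrecognized trial name {name!r}")
    stem, letter, digits = m.groups()
    mouse_id = int(digits)
    if stem == "bc":
        if letter is not None:
            raise TrialNameError(
                f"baseline name {name!r} must not carry a before/after letter"
            )
        return ConditionLabel(Antagonist.NONE, Order.BASELINE), mouse_id
    if letter is None:
        raise TrialNameError(
            f"antagonist name {name!r} is missing the before/after letter"
        )
    order = Order.BEFORE_COCAINE if letter == "b" else Order.AFTER_COCAINE
    return ConditionLabel(Antagonist(stem), order), mouse_id


@dataclass
class Trial:
    """One LFP sweep: samples plus sampling rate and identity metadata.

    Samples are in the (arbitrary) amplitude units of the acquisition
    chain; ``trial_index`` is 1-based, matching the "trial #5" convention.
    """

    samples: np.ndarray
    rate: float
    mouse_id: int = 0
    condition: ConditionLabel = field(default_factory=ConditionLabel)
    trial_index: int = 1

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trial samples must be one-dimensional")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trial samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def peak_to_peak(self) -> float:
        return float(np.ptp(self.samples))


@dataclass
class TrialSet:
    """An ordered ensemble of trials sharing rate, length and identity."""

    trials: list[Trial]
    label: ConditionLabel = field(default_factory=ConditionLabel)
    mouse_id: int = 0

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("a trial set needs at least one trial")
        n = self.trials[0].n_samples
        rate = self.trials[0].rate
        for t in self.trials:
            if t.n_samples != n or t.rate != rate:
                raise ValueError("all trials must share rate and length")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i: int) -> Trial:
        return self.trials[i]

    @property
    def rate(self) -> float:
        return self.trials[0].rate

    @property
    def n_samples(self) -> int:
        return self.trials[0].n_samples

    @property
    def name(self) -> str:
        return f"{self.label.short}{self.mouse_id}"

    def as_matrix(self) -> np.ndarray:
        """Trials stacked as rows of a (n_trials, n_samples) matrix."""
        return np.stack([t.samples for t in self.trials])

    def with_matrix(self, matrix: np.ndarray) -> "TrialSet":
        """Copy of the set with samples replaced row-by-row."""
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(self), self.n_samples):
            raise ValueError("matrix shape does not match the trial set")
        trials = [replace(t, samples=matrix[i]) for i, t in enumerate(self.trials)]
        return TrialSet(trials, label=self.label, mouse_id=self.mouse_id)


def trim_transient(obj: Trial | TrialSet, cut: float = 0.5):
    """Drop the first ``cut`` seconds (the stimulus transient) of each trial.

    The 10 ms light pulse phase-resets the network; the transient response
    occupies roughly the first half second of each sweep, so the analysis
    keeps only the steady activity that follows.
    """
    if isinstance(obj, TrialSet):
        trials = [trim_transient(t, cut) for t in obj.trials]
        return TrialSet(trials, label=obj.label, mouse_id=obj.mouse_id)
    trial = obj
    if cut < 0:
        raise ValueError("cut must be non-negative")
    if cut >= trial.duration:
        raise ValueError(
            f"cut {cut} s is not shorter than the trial duration {trial.duration} s"
        )
    n_cut = int(round(cut * trial.rate))
    return replace(trial, samples=trial.samples[n_cut:])


def concat_matrix(set_a: TrialSet, set_b: TrialSet) -> tuple[np.ndarray, np.ndarray]:
    """Stack two trial sets and return (matrix, is_baseline mask).

    Ordering follows the concatenation convention used for overlap
    analysis: trials of ``set_a`` (the baseline) first, then ``set_b``.
    """
    if set_a.rate != set_b.rate or set_a.n_samples != set_b.n_samples:
        raise ValueError("trial sets must share rate and trial length")
    mat = np.vstack([set_a.as_matrix(), set_b.as_matrix()])
    membership = np.array([True] * len(set_a) + [False] * len(set_b))
    return mat, membership


# ---------------------------------------------------------------------------
# File I/O
#
# Two plain formats are supported: an HDF5 layout (one dataset per set,
# metadata as attributes) and a CSV matrix (rows = trials, one metadata
# header line).  write o read is the identity on values within float
# tolerance: exact for HDF5, ~1e-6 relative for CSV.


def write_trialset(tset: TrialSet, path, fmt: str = "hdf5") -> None:
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            d = f.create_dataset("trials", data=tset.as_matrix())
            d.attrs["name"] = tset.name
            d.attrs["rate"] = tset.rate
            d.attrs["mouse_id"] = tset.mouse_id
    elif fmt == "csv":
        with open(path, "w") as f:
            f.write(f"name={tset.name},rate={tset.rate!r},mouse_id={tset.mouse_id}\n")
            for t in tset.trials:
                f.write(",".join(f"{v:.10g}" for v in t.samples) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_trialset(path, fmt: str = "hdf5") -> TrialSet:
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            d = f["trials"]
            mat = d[...]
            name = d.attrs["name"]
            rate = float(d.attrs["rate"])
        label, mouse_id = parse_trial_name(str(name))
    elif fmt == "csv":
        with open(path) as f:
            header = f.readline().strip()
            meta = dict(kv.split("=", 1) for kv in header.split(","))
            if "name" not in meta or "rate" not in meta:
                raise ValueError("csv header must carry name= and rate= metadata")
            rate = float(meta["rate"])
            label, mouse_id = parse_trial_name(meta["name"])
            rows = []
            for line_no, line in enumerate(f, start=2):
                line = line.strip()
                if not line:
                    continue
                rows.append(np.array([float(v) for v in line.split(",")]))
        if not rows:
            raise ValueError("csv file contains no trials")
        lengths = {r.size for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged csv input: row lengths {sorted(lengths)}")
        mat = np.stack(rows)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    trials = [
        Trial(mat[i], rate=rate, mouse_id=mouse_id, condition=label, trial_index=i + 1)
        for i in range(mat.shape[0])
    ]
    return TrialSet(trials, label=label, mouse_id=mouse_id)
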