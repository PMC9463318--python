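"""Maximum-likelihood CPT estimation from complete categorical records.

Rows are estimated in closed form with Dirichlet pseudocount smoothing:
``P(child=s | config) = (n_{config,s} + alpha) / (n_config + alpha * K)``.
The records are assumed complete (no missing cells); this mirrors a workflow
in which clinical data managers extract one fully coded row per patient.

Parent configurations never observed in the data are the diagnosed failure
mode of over-detailed models trained on small cohorts: with ``alpha = 0``
such rows are set uniform and surfaced through :func:`fit_report` rather
than hidden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import CPT, BayesianNetwork, ModelError

logger = logging.getLogger(__name__)


class DataError(ValueError):
    """Dataset does not match the model (columns, states, missing cells)."""


@dataclass
class PatientDataset:
    """Complete categorical patient records keyed by variable name.

    Thin wrapper over a string-valued :class:`pandas.DataFrame`; one row per
    patient, one column per model variable, each cell a state label.
    """

    df: pd.DataFrame
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.df = self.df.astype("object").reset_index(drop=True)
        if self.df.isna().any().any():
            rows, cols = np.where(self.df.isna())
            raise DataError(
                f"missing cell at row {int(rows[0])}, "
                f"column {self.df.columns[int(cols[0])]!r}"
            )

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_records(self) -> int:
        return len(self.df)

    def validate_against(self, network: BayesianNetwork) -> None:
        """Check every column is a network variable and every cell a legal
        state; raises :class:`DataError` with coordinates otherwise."""
        offending = []
        for col in self.columns:
            if col not in network:
                raise DataError(f"column {col!r} is not a model variable")
            states = set(network.variable(col).states)
            bad = ~self.df[col].isin(states)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                offending.append(
                    f"(row {row}, column {col!r}): {self.df.at[row, col]!r}"
                )
        if offending:
            raise DataError("illegal state values at " + "; ".join(offending))

    def covers(self, network: BayesianNetwork) -> bool:
        return all(name in self.columns for name in network.variable_names)

    def copy(self) -> "PatientDataset":
        return PatientDataset(self.df.copy(), self.provenance)


@dataclass(frozen=True)
class LearningConfig:
    """Pseudocount smoothing configuration.

    ``alpha`` is the Dirichlet pseudocount added per child state per parent
    configuration; ``alpha = 0`` gives the raw MLE (with uniform fallback for
    unseen configurations), ``alpha -> inf`` pulls every row to uniform.
    """

    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ModelError(f"alpha must be finite and >= 0, got {self.alpha!r}")


def _codes(dataset: PatientDataset, network: BayesianNetwork, name: str) -> np.ndarray:
    states = network.variable(name).states
    codes = pd.Categorical(dataset.df[name], categories=states).codes
    if (codes < 0).any():
        row = int(np.flatnonzero(codes < 0)[0])
        raise DataError(
            f"(row {row}, column {name!r}): {dataset.df.at[row, name]!r} "
            f"is not a state of {name!r}"
        )
    return codes.astype(np.int64)


def count_table(
    network: BayesianNetwork,
    dataset: PatientDataset,
    child: str,
    parents: Sequence[str] | None = None,
) -> np.ndarray:
    """Joint counts per (parent configuration, child state).

    Returns an integer array of shape ``(n_parent_configs, n_child_states)``
    in CPT row order; entries total the record count.  ``parents`` defaults
    to the child's parents in ``network``.
    """
    if parents is None:
        parents = network.parents(child)
    for name in (child, *parents):
        if name not in dataset.columns:
            raise DataError(f"column {name!r} not in dataset")
    child_var = network.variable(child)
    cards = [network.variable(p).n_states for p in parents]
    n_rows = int(np.prod(cards, dtype=np.int64))
    counts = np.zeros((n_rows, child_var.n_states), dtype=np.int64)
    if dataset.n_records == 0:
        return counts
    row_idx = np.zeros(dataset.n_records, dtype=np.int64)
    for p, card in zip(parents, cards):
        row_idx = row_idx * card + _codes(dataset, network, p)
    np.add.at(counts, (row_idx, _codes(dataset, network, child)), 1)
    return counts


def learn_cpts(
    network: BayesianNetwork,
    dataset: PatientDataset,
    config: LearningConfig = LearningConfig(),
) -> BayesianNetwork:
    """Fit every CPT of ``network`` from ``dataset`` by smoothed MLE.

    With ``alpha = 0``, unseen parent configurations get a uniform row (and a
    debug log entry); :func:`fit_report` quantifies how many there are.
    """
    missing = [n for n in network.variable_names if n not in dataset.columns]
    if missing:
        raise DataError(f"dataset lacks columns for variables: {missing}")
    dataset.validate_against(network)
    new_cpts: dict[str, CPT] = {}
    for var in network.variables:
        old = network.cpt(var.name)
        counts = count_table(network, dataset, var.name, old.parents).astype(float)
        totals = counts.sum(axis=1, keepdims=True)
        k = var.n_states
        if config.alpha > 0:
            table = (counts + config.alpha) / (totals + config.alpha * k)
        else:
            table = np.full_like(counts, 1.0 / k)
            seen = totals[:, 0] > 0
            table[seen] = counts[seen] / totals[seen]
            n_unseen = int((~seen).sum())
            if n_unseen:
                logger.debug(
                    "%s: %d/%d parent configurations unseen; rows set uniform",
                    var.name,
                    n_unseen,
                    counts.shape[0],
                )
        new_cpts[var.name] = CPT(var.name, old.parents, table)
    return network.with_cpts(new_cpts)


@dataclass
class FitReport:
    """Coverage summary: fraction of parent configurations observed >= once.

    A low coverage (``density of information``) on a high-arity node signals
    that the learned CPT is dominated by smoothing or uniform fallbacks.
    """

    coverage: dict[str, float]
    observed_configs: dict[str, int]
    total_configs: dict[str, int]
    n_records: int

    @property
    def overall_min(self) -> float:
        return min(self.coverage.values())

    def low_coverage(self, threshold: float = 1.0) -> dict[str, float]:
        return {n: c for n, c in self.coverage.items() if c < threshold}


def fit_report(network: BayesianNetwork, dataset: PatientDataset) -> FitReport:
    """Per-variable parent-configuration coverage of ``dataset``."""
    dataset.validate_against(network)
    coverage, observed, total = {}, {}, {}
    for var in network.variables:
        counts = count_table(network, dataset, var.name)
        seen = int((counts.sum(axis=1) > 0).sum())
        coverage[var.name] = seen / counts.shape[0]
        observed[var.name] = seen
        total[var.name] = int(counts.shape[0])
    return FitReport(coverage, observed, total, dataset.n_records)
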