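"""MAP bicluster assignment and partition agreement.

A fitted model induces the biclustering directly: observations go to the
component with the largest responsibility (MAP), variables keep the
cluster labels carried by the supplied loadings matrix, and the biclusters
are the G x q cells of the resulting grid — non-overlapping and
exhaustive in both dimensions.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .core import BiclusterAssignment, FitResult, LoadingsSpec


def map_classify(zhat: np.ndarray) -> np.ndarray:
    """Per-row argmax of the responsibilities; ties go to the lowest index.

    Returns 0-based component labels.
    """
    zhat = np.asarray(zhat, dtype=float)
    return np.argmax(zhat, axis=1)


def adjusted_rand_index(truth, predicted) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions.

    Chance-corrected pair agreement: 1 for identical partitions up to
    relabelling, expectation ~0 for independent random ones.  Computed in
    closed form from the contingency table (scikit-learn), which also
    yields 1 when both partitions are the same single cluster.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("partitions must have equal length")
    return float(adjusted_rand_score(truth, predicted))


def assemble_biclusters(fit: FitResult, spec: LoadingsSpec) -> BiclusterAssignment:
    """Turn a fit into the G x q grid with row/column display orders.

    Rows are ordered by MAP component and columns by variable cluster,
    both with a stable sort so equal labels keep their input order; the
    reordered matrix then shows contiguous blocks.
    """
    if fit.failed or fit.zhat is None:
        raise ValueError("cannot assemble biclusters from a failed fit")
    obs_labels = map_classify(fit.zhat)
    var_labels = spec.var_labels()
    return BiclusterAssignment(
        obs_labels=obs_labels,
        var_labels=var_labels,
        G=fit.params.G,
        q=spec.q,
    )


def write_assignment(assignment: BiclusterAssignment, fit: FitResult,
                     row_ids, tsv_path, json_path=None) -> None:
    """Serialize: per-observation TSV (id, MAP component, max zhat) and an
    optional JSON summary of the G x q grid.  Cluster indices are 1-based
    in all user-facing files."""
    max_z = fit.zhat[np.arange(fit.zhat.shape[0]), assignment.obs_labels]
    pd.DataFrame({
        "observation_id": list(row_ids),
        "MAP_component": assignment.obs_labels + 1,
        "max_zhat": max_z,
    }).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        summary = {
            "G": assignment.G,
            "q": assignment.q,
            "grid_sizes": assignment.grid.tolist(),
            "observations_per_component": np.bincount(
                assignment.obs_labels, minlength=assignment.G
            ).tolist(),
            "variables_per_cluster": np.bincount(
                assignment.var_labels, minlength=assignment.q
            ).tolist(),
        }
        with open(json_path, "w") as fh:
            json.dump(summary, fh, indent=2)
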