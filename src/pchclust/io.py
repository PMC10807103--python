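"""File formats: feature matrices, prior pair lists, fit and result tables.

Feature matrices are delimited text, samples x features, with a header row
of feature names and a first column of sample IDs.  Prior pair files are
two-column delimited text (sample-ID, sample-ID) with '#' comments; IDs
are resolved against the feature-matrix row names.  All on-disk sample
numbering is 1-based where numeric; internal indices are 0-based.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .extraction import ClusteringResult
from .prior import PriorPairSet, validate_and_close
from .solver import HierarchicalDataset, PCHState


def read_dataset(x_path, z_path) -> HierarchicalDataset:
    """Read X and Z matrices and join them on sample ID (order of X wins)."""
    xdf = pd.read_csv(x_path, index_col=0)
    zdf = pd.read_csv(z_path, index_col=0)
    zdf.index = zdf.index.astype(str)
    xdf.index = xdf.index.astype(str)
    missing = xdf.index.difference(zdf.index)
    if len(missing):
        raise ValueError(f"samples absent from Z: {list(missing)[:5]} ...")
    zdf = zdf.loc[xdf.index]
    return HierarchicalDataset(
        X=xdf.to_numpy().T, Z=zdf.to_numpy().T, sample_ids=tuple(xdf.index)
    )


def write_dataset(data: HierarchicalDataset, x_path, z_path):
    pd.DataFrame(
        data.X.T, index=list(data.sample_ids),
        columns=[f"x{j + 1}" for j in range(data.q)],
    ).to_csv(x_path, index_label="sample")
    pd.DataFrame(
        data.Z.T, index=list(data.sample_ids),
        columns=[f"z{j + 1}" for j in range(data.p)],
    ).to_csv(z_path, index_label="sample")


def read_prior(path, sample_ids) -> PriorPairSet:
    """Two-column pair list resolved against sample IDs; closed on read."""
    pos = {str(s): i for i, s in enumerate(sample_ids)}
    raw = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.replace(",", "\t").split()
            if len(fields) != 2:
                raise ValueError(f"expected two sample IDs per line, got {line!r}")
            try:
                raw.append((pos[fields[0]], pos[fields[1]]))
            except KeyError as exc:
                raise ValueError(f"unknown sample ID {exc.args[0]!r}") from None
    return validate_and_close(raw, len(sample_ids))


def write_prior(prior: PriorPairSet, sample_ids, path):
    with open(path, "w") as fh:
        fh.write("# must-link sample pairs\n")
        for j, m in sorted(prior.pairs):
            fh.write(f"{sample_ids[j]}\t{sample_ids[m]}\n")


def write_result(result: ClusteringResult, sample_ids, path):
    """Per-sample label table; labels printed 1-based."""
    pd.DataFrame(dict(
        sample=list(sample_ids),
        rough=result.rough_labels + 1,
        refined=result.refined_labels + 1,
    )).to_csv(path, index=False)


def write_state(state: PCHState, path):
    """Serialize the fitted centers and diagnostics as JSON."""
    payload = dict(
        beta=state.beta.tolist(), gamma=state.gamma.tolist(),
        lambda1=state.lambda1, lambda2=state.lambda2,
        theta=state.theta, a=state.a,
        iteration=state.iteration, converged=bool(state.converged),
        final_residual=state.residuals[-1] if state.residuals else None,
    )
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_state_centers(path):
    with open(path) as fh:
        payload = json.load(fh)
    return np.asarray(payload["beta"]), np.asarray(payload["gamma"]), payload
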