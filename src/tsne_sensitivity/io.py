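"""Writers for the analysis artifacts (TSV / JSON / HDF5).

Text formats are the default: an embedding is a small TSV plus a JSON
sidecar with its convergence certificate; the Jacobian goes to a labeled
TSV (rows "sample:axis", columns "sample:feature") with an HDF5 option for
large instances; the output covariance is dense HDF5 with a JSON summary.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datasets import Dataset
from .optimize import Embedding, TsneConfig
from .propagation import HypotheticalOutcomes, OutputCovariance
from .sensitivity import SensitivityJacobian

__all__ = [
    "write_embedding",
    "read_embedding",
    "write_jacobian_tsv",
    "write_jacobian_hdf5",
    "write_spectrum_json",
    "write_covariance_hdf5",
    "write_covariance_summary_json",
    "write_outcomes_tsv",
]


def write_embedding(emb: Embedding, path: str | Path,
                    sample_names: list[str] | None = None) -> Path:
    """Embedding as TSV (sample_name, dim1, dim2, ...) + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = sample_names or [f"sample{i}" for i in range(emb.n_samples)]
    cols = {f"dim{a + 1}": emb.coords[:, a] for a in range(emb.out_dim)}
    pd.DataFrame({"sample_name": names, **cols}).to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(emb.to_json_dict(), indent=2))
    return path


def read_embedding(path: str | Path) -> Embedding:
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    coords = table[[c for c in table.columns if c.startswith("dim")]].to_numpy(float)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        cfg_dict = dict(meta["config"])
        cfg_dict["momentum"] = tuple(cfg_dict["momentum"])
        cfg = TsneConfig(**cfg_dict)
        return Embedding(coords, meta["final_grad_maxnorm"], meta["converged"], cfg)
    return Embedding(coords, np.inf, False, TsneConfig())


def write_jacobian_tsv(jac: SensitivityJacobian, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(jac.values, index=jac.row_labels(), columns=jac.col_labels())
    frame.to_csv(path, sep="\t")
    return path


def write_jacobian_hdf5(jac: SensitivityJacobian, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("jacobian", data=jac.values)
        f.create_dataset("row_labels", data=np.array(jac.row_labels(), dtype="S"))
        f.create_dataset("col_labels", data=np.array(jac.col_labels(), dtype="S"))
        f.attrs["gauge"] = jac.gauge
    return path


def write_spectrum_json(jac: SensitivityJacobian, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(jac.spectrum.summary(), indent=2))
    return path


def write_covariance_hdf5(cov: OutputCovariance, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("covariance", data=cov.values)
        f.create_dataset("point_marginals", data=np.stack(cov.point_marginals))
    return path


def write_covariance_summary_json(cov: OutputCovariance, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(cov.summary(), indent=2))
    return path


def write_outcomes_tsv(outcomes: HypotheticalOutcomes, path: str | Path,
                       sample_names: list[str] | None = None) -> Path:
    """Frame stack as long-format TSV: frame, sample_name, dim1, dim2, ..."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    K, n, p = outcomes.frames.shape
    names = sample_names or [f"sample{i}" for i in range(n)]
    rows = {
        "frame": np.repeat(np.arange(K), n),
        "sample_name": np.tile(names, K),
    }
    flat = outcomes.frames.reshape(K * n, p)
    for a in range(p):
        rows[f"dim{a + 1}"] = flat[:, a]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_uncertainty(path: str | Path, like: Dataset | None = None):
    """Read a per-entry variance matrix in the same layout as a Dataset."""
    from .datasets import read_dataset
    from .propagation import InputUncertainty

    var = read_dataset(path)
    if like is not None:
        if var.values.shape != like.values.shape:
            raise ValueError(
                f"variance matrix shape {var.values.shape} does not match "
                f"data shape {like.values.shape}"
            )
    return InputUncertainty(variances=var.values)
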