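"""File-format contracts shared by all stages.

Everything is TSV with a header row (gzip optional) except the 3-D founder
probability array, which lives in HDF5 with one (marker x sample x 8) dataset
per chromosome. Coordinates are 1-based; founder order AJ, B6, 129, NOD, NZO,
CAST, PWK, WSB.
"""

from __future__ import annotations

import json
import os

import h5py
import numpy as np
import pandas as pd

from .simulate import GenotypeProbs


def write_samples(samples: pd.DataFrame, path: str) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_samples(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "age_years" not in df.columns and "age_months" in df.columns:
        df["age_years"] = df["age_months"] / 12.0
    return df


def write_matrix(matrix: pd.DataFrame, path: str, index_name: str = "gene_id") -> None:
    matrix.rename_axis(index_name).to_csv(path, sep="\t")


def read_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_probs(probs: GenotypeProbs, h5_path: str, markers_path: str = None) -> None:
    with h5py.File(h5_path, "w") as fh:
        fh.attrs["founders"] = "AJ,B6,129,NOD,NZO,CAST,PWK,WSB"
        fh.create_dataset("samples", data=np.array(probs.sample_ids, dtype="S"))
        for c, sub in probs.markers.groupby("chromosome", sort=False):
            sel = sub.index.to_numpy()
            fh.create_dataset(f"probs/{c}", data=probs.probs[sel])
    if markers_path:
        probs.markers.to_csv(markers_path, sep="\t", index=False)


def read_probs(h5_path: str, markers_path: str) -> GenotypeProbs:
    markers = pd.read_csv(markers_path, sep="\t")
    with h5py.File(h5_path, "r") as fh:
        samples = [s.decode() for s in fh["samples"][:]]
        blocks = []
        for c, sub in markers.groupby("chromosome", sort=False):
            blocks.append(fh[f"probs/{c}"][:])
    return GenotypeProbs(markers=markers, sample_ids=samples,
                         probs=np.concatenate(blocks, axis=0))


def read_peptides(path: str) -> pd.DataFrame:
    # variant_mask is an 8-char 0/1 string; plain read would drop leading 0s
    return pd.read_csv(path, sep="\t", dtype={"variant_mask": str})


def write_json(obj, path: str) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_default)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
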