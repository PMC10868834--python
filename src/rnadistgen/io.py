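"""File formats: FASTA sequences, SHAPE TSV profiles, HDF5 tensor and
ensemble stores, YAML run configuration."""

from __future__ import annotations

import numpy as np


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper().replace("T", "U"))
            for rec in SeqIO.parse(str(path), "fasta")]


def read_shape_tsv(path, length: int | None = None) -> np.ndarray:
    """Two-column TSV (1-based position, reactivity) -> dense vector."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["pos", "reactivity"])
    n = length or int(df["pos"].max())
    out = np.zeros(n)
    for _, row in df.iterrows():
        out[int(row["pos"]) - 1] = float(row["reactivity"])
    return out


def write_tensor_h5(path, tensor) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("D", data=tensor.D)
        fh.create_dataset("M", data=tensor.M)
        fh.attrs["L"] = tensor.L


def read_tensor_h5(path):
    import h5py

    from .codec import DistanceTensor

    with h5py.File(path, "r") as fh:
        return DistanceTensor(fh["D"][...], fh["M"][...], int(fh.attrs["L"]))


def write_ensemble_h5(path, maps, metadata=None) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        for i, cm in enumerate(maps):
            g = fh.create_group(f"map{i:04d}")
            g.create_dataset("classes", data=cm.classes)
            g.attrs["K"] = cm.K
            for k, v in ((metadata or [{}] * len(maps))[i]).items():
                g.attrs[k] = v


def read_ensemble_h5(path):
    import h5py

    from .vqvae import ClassMap

    maps = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh):
            g = fh[name]
            maps.append(ClassMap(g["classes"][...], int(g.attrs["K"])))
    return maps


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh) or {}
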