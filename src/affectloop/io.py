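"""Serialization: TSV tables, BIDS-style events, HDF5 array containers."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from affectloop.decoder import BetaSeries, DecoderModel
from affectloop.encoding import EncodingMap
from affectloop.synthetic import StimulusCatalog, VolumeSeries, validate_schedule

FORMAT_VERSION = 1


# --- TSV -------------------------------------------------------------------


def write_catalog(catalog: StimulusCatalog, path) -> None:
    catalog.frame.to_csv(path, sep="\t", index=False)


def read_catalog(path) -> StimulusCatalog:
    return StimulusCatalog(pd.read_csv(path, sep="\t"))


def write_events(schedule: pd.DataFrame, path) -> None:
    validate_schedule(schedule)
    schedule.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    schedule = pd.read_csv(path, sep="\t")
    validate_schedule(schedule)
    return schedule


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --- HDF5 array containers -------------------------------------------------


def write_volume_series(series: VolumeSeries, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=series.data)
        d.attrs["tr"] = series.tr
        d.attrs["t0"] = series.t0
        f.attrs["format_version"] = FORMAT_VERSION


def read_volume_series(path) -> VolumeSeries:
    with h5py.File(path, "r") as f:
        d = f["data"]
        return VolumeSeries(data=d[()], tr=float(d.attrs["tr"]), t0=float(d.attrs["t0"]))


def write_decoder(model: DecoderModel, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=model.weights)
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["offset"] = model.offset
        f.attrs["dimension"] = model.dimension
        for name in ("platt_a", "platt_b", "accuracy_full", "accuracy_reliable"):
            value = getattr(model, name)
            if value is not None:
                f.attrs[name] = value


def read_decoder(path) -> DecoderModel:
    with h5py.File(path, "r") as f:
        kwargs = {
            name: float(f.attrs[name])
            for name in ("platt_a", "platt_b", "accuracy_full", "accuracy_reliable")
            if name in f.attrs
        }
        return DecoderModel(
            weights=f["weights"][()],
            offset=float(f.attrs["offset"]),
            dimension=str(f.attrs["dimension"]),
            **kwargs,
        )


def write_beta_series(betas: BetaSeries, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("maps", data=betas.maps)
        f.create_dataset(
            "tags", data=np.array([str(t) for t in betas.tags], dtype=h5py.string_dtype())
        )
        f.attrs["format_version"] = FORMAT_VERSION


def read_beta_series(path) -> BetaSeries:
    with h5py.File(path, "r") as f:
        tags = [t.decode() if isinstance(t, bytes) else str(t) for t in f["tags"][()]]
        return BetaSeries(tags=tags, maps=f["maps"][()])


def write_encoding_map(emap: EncodingMap, path, alpha: float = 0.05) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=emap.values)
        f.create_dataset("mask", data=emap.mask)
        f.create_dataset("p_values", data=emap.p_values)
        f.attrs["dimension"] = emap.dimension
        f.attrs["alpha"] = alpha
        f.attrs["format_version"] = FORMAT_VERSION


def read_encoding_map(path) -> EncodingMap:
    with h5py.File(path, "r") as f:
        return EncodingMap(
            values=f["values"][()],
            mask=f["mask"][()],
            p_values=f["p_values"][()],
            dimension=str(f.attrs["dimension"]),
        )


# --- reports ---------------------------------------------------------------


def write_fit_results(results: dict, path) -> None:
    """Serialize a (possibly nested) dict of FitResult-like objects to JSON."""

    def convert(obj):
        if hasattr(obj, "to_dict"):
            return convert(obj.to_dict())
        if isinstance(obj, dict):
            return {str(k): convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if hasattr(obj, "pvalue"):  # scipy test results
            return {"statistic": float(obj.statistic), "pvalue": float(obj.pvalue)}
        if hasattr(obj, "__dataclass_fields__"):
            return convert(vars(obj))
        return obj

    Path(path).write_text(json.dumps(convert(results), indent=2))
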