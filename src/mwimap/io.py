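"""NIfTI volume I/O with JSON protocol sidecars.

Every dataset is a NIfTI-1 volume (4th dimension = echo or flip-angle
index) plus a JSON sidecar holding the acquisition parameters in fixed
units (ms, degrees). Sidecars round-trip losslessly to the protocol
dataclasses.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .epg import EchoTrainSpec
from .ssmodels import SteadyStateProtocol

__all__ = [
    "write_volume",
    "read_volume",
    "sidecar_path",
    "protocol_to_sidecar",
    "sidecar_to_protocol",
]


def sidecar_path(path) -> Path:
    """JSON sidecar path of a NIfTI file (.nii or .nii.gz)."""
    p = Path(path)
    name = p.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return p.with_name(name[: -len(suf)] + ".json")
    return p.with_suffix(".json")


def protocol_to_sidecar(protocol) -> dict:
    """Serialize an acquisition protocol to a sidecar dict (ms / degrees)."""
    if isinstance(protocol, EchoTrainSpec):
        return {
            "sequence": "multi_echo_se",
            "te_first_ms": protocol.te_first,
            "delta_te_ms": protocol.delta_te,
            "n_echoes": protocol.n_echoes,
            "tr_ms": protocol.tr,
        }
    if isinstance(protocol, SteadyStateProtocol):
        return {
            "sequence": "steady_state_session",
            "spgr_tr_ms": protocol.spgr_tr,
            "spgr_te_ms": protocol.spgr_te,
            "spgr_fas_deg": list(protocol.spgr_fas),
            "irspgr_tr_ms": protocol.irspgr_tr,
            "irspgr_te_ms": protocol.irspgr_te,
            "irspgr_ti_ms": protocol.irspgr_ti,
            "irspgr_fa_deg": protocol.irspgr_fa,
            "bssfp_tr_ms": protocol.bssfp_tr,
            "bssfp_te_ms": protocol.bssfp_te,
            "bssfp_fas_deg": list(protocol.bssfp_fas),
            "phase_cycles_deg": list(protocol.phase_cycles),
        }
    raise TypeError(f"unsupported protocol type: {type(protocol)!r}")


def sidecar_to_protocol(sidecar: dict):
    """Rebuild the protocol dataclass recorded in a sidecar dict."""
    kind = sidecar.get("sequence")
    if kind == "multi_echo_se":
        return EchoTrainSpec(
            te_first=float(sidecar["te_first_ms"]),
            delta_te=float(sidecar["delta_te_ms"]),
            n_echoes=int(sidecar["n_echoes"]),
            tr=float(sidecar["tr_ms"]),
        )
    if kind == "steady_state_session":
        return SteadyStateProtocol(
            spgr_tr=float(sidecar["spgr_tr_ms"]),
            spgr_te=float(sidecar["spgr_te_ms"]),
            spgr_fas=tuple(float(f) for f in sidecar["spgr_fas_deg"]),
            irspgr_tr=float(sidecar["irspgr_tr_ms"]),
            irspgr_te=float(sidecar["irspgr_te_ms"]),
            irspgr_ti=float(sidecar["irspgr_ti_ms"]),
            irspgr_fa=float(sidecar["irspgr_fa_deg"]),
            bssfp_tr=float(sidecar["bssfp_tr_ms"]),
            bssfp_te=float(sidecar["bssfp_te_ms"]),
            bssfp_fas=tuple(float(f) for f in sidecar["bssfp_fas_deg"]),
            phase_cycles=tuple(float(f) for f in sidecar["phase_cycles_deg"]),
        )
    raise ValueError(f"unknown sequence kind in sidecar: {kind!r}")


def write_volume(path, data, affine=None, sidecar: dict | None = None) -> Path:
    """Write a volume as NIfTI-1 (+ JSON sidecar if given). Returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    nib.save(img, str(path))
    if sidecar is not None:
        sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_volume(path, require_sidecar: bool = False):
    """Read a NIfTI volume: (data, affine, sidecar dict or None).

    With ``require_sidecar`` a missing JSON sidecar is an explicit error.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    sp = sidecar_path(path)
    sidecar = None
    if sp.exists():
        sidecar = json.loads(sp.read_text())
    elif require_sidecar:
        raise FileNotFoundError(f"missing protocol sidecar: {sp}")
    return data, img.affine, sidecar
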