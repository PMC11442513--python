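"""Recording I/O, bipolar montage derivation, and structure assignment.

A hemisphere is recorded from a single depth electrode with eight circular
contacts spanning striatum, external pallidum (GPe) and internal pallidum
(GPi). Contacts are ordered ventral to dorsal; adjacent-contact bipolar
derivations give seven parallel channels per hemisphere, of which only those
whose *both* contacts lie inside the same nucleus are retained for analysis.

Native on-disk format: a little-endian float64 channel-major binary matrix
(``.dat``) or a tab-separated text matrix (``.tsv``, one column per contact),
either way accompanied by a JSON sidecar carrying the sampling rate, contact
labels (ventral to dorsal) and the contact-to-structure mapping.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Nuclei that can be assigned to a bipolar channel.
STRUCTURES = ("STR", "GPe", "GPi")

#: Label used for contacts outside any nucleus of interest.
OTHER = "other"

_HEMISPHERES = ("left", "right")


@dataclass
class Recording:
    """Multichannel monopolar (or pre-bipolarized) recording of one hemisphere.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    hemisphere : {"left", "right"}
    fs : float
        Sampling rate in Hz.
    contacts : list of str
        Contact labels in ventral-to-dorsal order; adjacency in this list
        defines the bipolar montage.
    samples : ndarray, shape (n_contacts, n_times)
        Voltage traces, arbitrary units.
    contact_structure : dict
        Maps each contact label to ``"STR"``, ``"GPe"``, ``"GPi"`` or
        ``"other"``. Unknown structure names are coerced to ``"other"``.
    bipolar : bool
        True when ``samples`` rows are already bipolar derivations, in which
        case :func:`derive_bipolar` must not be applied again.
    """

    subject_id: str
    hemisphere: str
    fs: float
    contacts: list[str]
    samples: np.ndarray
    contact_structure: dict[str, str] = field(default_factory=dict)
    bipolar: bool = False

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.hemisphere not in _HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {_HEMISPHERES}, got {self.hemisphere!r}")
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D [contacts x time] matrix")
        if self.samples.shape[0] != len(self.contacts):
            raise ValueError(
                f"channel count mismatch: {self.samples.shape[0]} sample rows "
                f"but {len(self.contacts)} contact labels"
            )
        clean = {}
        for c in self.contacts:
            s = self.contact_structure.get(c, OTHER)
            clean[c] = s if s in STRUCTURES else OTHER
        self.contact_structure = clean

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class BipolarChannel:
    """Adjacent-contact bipolar derivation (ventral minus dorsal contact)."""

    pair: tuple[str, str]
    samples: np.ndarray
    structure: str | None = None


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording to ``path`` (``.dat`` binary or ``.tsv`` text) plus
    a JSON sidecar ``<path>.json``. Returns the sidecar path."""
    path = Path(path)
    if path.suffix == ".tsv":
        header = "\t".join(rec.contacts)
        np.savetxt(path, rec.samples.T, delimiter="\t", header=header, comments="", fmt="%.10g")
    else:
        rec.samples.astype("<f8").tofile(path)
    meta = {
        "subject_id": rec.subject_id,
        "hemisphere": rec.hemisphere,
        "fs": rec.fs,
        "contacts": list(rec.contacts),
        "contact_structure": dict(rec.contact_structure),
        "n_samples": int(rec.n_samples),
        "bipolar": rec.bipolar,
    }
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def read_recording(path: str | Path, metadata_path: str | Path | None = None) -> Recording:
    """Read a recording written by :func:`write_recording`.

    ``metadata_path`` defaults to ``<path>.json``. Raises a ``ValueError``
    naming the offending field when the sidecar is incomplete or inconsistent
    with the data matrix.
    """
    path = Path(path)
    if metadata_path is None:
        metadata_path = path.with_suffix(path.suffix + ".json")
    metadata_path = Path(metadata_path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if not metadata_path.exists():
        raise FileNotFoundError(f"sidecar metadata not found: {metadata_path}")
    meta = json.loads(metadata_path.read_text())
    for key in ("fs", "contacts"):
        if key not in meta:
            raise ValueError(f"sidecar is missing required field {key!r}")
    contacts = list(meta["contacts"])
    if path.suffix == ".tsv":
        data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2).T
    else:
        flat = np.fromfile(path, dtype="<f8")
        if len(contacts) == 0 or flat.size % len(contacts) != 0:
            raise ValueError(
                f"binary file size ({flat.size} values) is not divisible by the "
                f"declared contact count ({len(contacts)})"
            )
        data = flat.reshape(len(contacts), -1)
    if data.shape[0] != len(contacts):
        raise ValueError(
            f"contacts field lists {len(contacts)} labels but file has {data.shape[0]} channels"
        )
    if "n_samples" in meta and int(meta["n_samples"]) != data.shape[1]:
        raise ValueError(
            f"n_samples field ({meta['n_samples']}) does not match file length ({data.shape[1]})"
        )
    return Recording(
        subject_id=str(meta.get("subject_id", "unknown")),
        hemisphere=str(meta.get("hemisphere", "left")),
        fs=float(meta["fs"]),
        contacts=contacts,
        samples=data,
        contact_structure=dict(meta.get("contact_structure", {})),
        bipolar=bool(meta.get("bipolar", False)),
    )


def derive_bipolar(rec: Recording) -> list[BipolarChannel]:
    """Derive the adjacent-pair bipolar montage (ventral minus dorsal).

    Eight contacts give seven parallel bipolar channels. The structure label
    is set only when both member contacts lie in the same nucleus.
    """
    if rec.bipolar:
        raise ValueError("recording is already bipolarized; montage derivation does not apply")
    if len(rec.contacts) < 2:
        raise ValueError("at least two contacts are required for a bipolar montage")
    channels = []
    for i in range(len(rec.contacts) - 1):
        a, b = rec.contacts[i], rec.contacts[i + 1]
        sa = rec.contact_structure.get(a, OTHER)
        sb = rec.contact_structure.get(b, OTHER)
        structure = sa if (sa == sb and sa in STRUCTURES) else None
        channels.append(
            BipolarChannel(pair=(a, b), samples=rec.samples[i] - rec.samples[i + 1], structure=structure)
        )
    return channels


def assign_structures(
    channels: list[BipolarChannel],
    mapping: dict[str, str] | None = None,
) -> dict[str, BipolarChannel]:
    """Retain one bipolar channel per nucleus.

    A channel is a candidate for a nucleus iff both its contacts map to that
    nucleus; all mixed-structure pairs are discarded. When several adjacent
    pairs lie fully inside the same nucleus, the most ventral pair (first in
    montage order) is retained — a declared tie-break.

    Parameters
    ----------
    channels : list of BipolarChannel
        Montage-ordered bipolar channels (ventral to dorsal).
    mapping : dict, optional
        Contact-to-structure mapping overriding the labels already attached
        to the channels.

    Returns
    -------
    dict mapping structure name -> retained BipolarChannel. Structures with
    no fully-contained pair are absent. Emits a warning (not an error) when
    nothing is retained.
    """
    retained: dict[str, BipolarChannel] = {}
    for ch in channels:
        if mapping is not None:
            sa = mapping.get(ch.pair[0], OTHER)
            sb = mapping.get(ch.pair[1], OTHER)
            structure = sa if (sa == sb and sa in STRUCTURES) else None
        else:
            structure = ch.structure
        if structure is None:
            continue
        if structure not in retained:  # most-ventral tie-break
            retained[structure] = BipolarChannel(ch.pair, ch.samples, structure)
    if not retained:
        warnings.warn("no bipolar pair lies fully within a single structure; nothing retained")
    return retained
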