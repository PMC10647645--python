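"""ROI-to-network definitions.

A :class:`NetworkDefinition` maps named functional networks (e.g. DMN, DAN,
SAN, VIS) to ordered lists of ROI labels.  The name ``"brain"`` is reserved
and always denotes the union of all ROIs across the named networks.
"""

from __future__ import annotations

from collections.abc import Mapping
from importlib import resources
from typing import Iterator

import yaml

BRAIN = "brain"


class NetworkDefinition(Mapping):
    """Partition of ROI labels into named networks.

    Parameters
    ----------
    networks
        Mapping from network name to an ordered list of ROI labels.  No ROI
        may appear in two networks, no network may be empty, and the name
        ``"brain"`` is reserved for the union of all ROIs.
    """

    def __init__(self, networks: Mapping[str, list[str]]):
        if BRAIN in networks:
            raise ValueError(
                f"network name {BRAIN!r} is reserved for the union of all ROIs"
            )
        seen: dict[str, str] = {}
        clean: dict[str, tuple[str, ...]] = {}
        for name, rois in networks.items():
            rois = tuple(str(r) for r in rois)
            if not rois:
                raise ValueError(f"network {name!r} is empty")
            for roi in rois:
                if roi in seen:
                    raise ValueError(
                        f"ROI {roi!r} appears in both {seen[roi]!r} and {name!r}"
                    )
                seen[roi] = name
            clean[str(name)] = rois
        if not clean:
            raise ValueError("at least one network is required")
        self._networks = clean

    # -- Mapping interface -------------------------------------------------
    def __getitem__(self, name: str) -> tuple[str, ...]:
        if name == BRAIN:
            return self.roi_labels
        return self._networks[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._networks)

    def __len__(self) -> int:
        return len(self._networks)

    def __repr__(self) -> str:
        sizes = ", ".join(f"{k}={len(v)}" for k, v in self._networks.items())
        return f"NetworkDefinition({sizes}; {len(self.roi_labels)} ROIs)"

    # -- derived views -----------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        """Named networks, excluding the reserved ``"brain"``."""
        return tuple(self._networks)

    @property
    def names_with_brain(self) -> tuple[str, ...]:
        return self.names + (BRAIN,)

    @property
    def roi_labels(self) -> tuple[str, ...]:
        """All ROI labels in network order (the ``"brain"`` network)."""
        return tuple(r for rois in self._networks.values() for r in rois)

    def network_of(self, roi: str) -> str:
        for name, rois in self._networks.items():
            if roi in rois:
                return name
        raise KeyError(f"unknown ROI label {roi!r}")

    def indices(self, name: str, roi_labels: list[str] | tuple[str, ...]) -> list[int]:
        """Positions of a network's ROIs inside an ordered label list."""
        pos = {lab: i for i, lab in enumerate(roi_labels)}
        out = []
        for roi in self[name]:
            if roi not in pos:
                raise KeyError(f"ROI label {roi!r} not present in epoch labels")
            out.append(pos[roi])
        return out

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, list[str]]:
        return {k: list(v) for k, v in self._networks.items()}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "NetworkDefinition":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"network definition file {path} must map names to ROI lists")
        return cls(data)

    @classmethod
    def evenly_partitioned(
        cls,
        roi_count: int,
        names: tuple[str, ...] = ("DMN", "DAN", "SAN", "VIS"),
        prefix: str = "roi",
    ) -> "NetworkDefinition":
        """Partition ``roi_count`` synthetic ROI labels evenly across networks.

        Intended for small test cohorts; labels are ``roi00, roi01, ...`` and
        each network receives a contiguous block (remainders go to the first
        networks).
        """
        if roi_count < len(names):
            raise ValueError(
                f"roi_count={roi_count} smaller than number of networks {len(names)}"
            )
        labels = [f"{prefix}{i:02d}" for i in range(roi_count)]
        base, extra = divmod(roi_count, len(names))
        nets: dict[str, list[str]] = {}
        start = 0
        for i, name in enumerate(names):
            size = base + (1 if i < extra else 0)
            nets[name] = labels[start : start + size]
            start += size
        return cls(nets)


def default_network_map() -> NetworkDefinition:
    """Whole-cortex 68-ROI default mapping shipped with the package.

    The labels follow a standard 34-regions-per-hemisphere cortical
    parcellation; the assignment of every region to exactly one of
    DMN/DAN/SAN/VIS is a coarse editable default for synthetic cohorts —
    real analyses should supply their own mapping file.
    """
    ref = resources.files("dynconn").joinpath("data/dk_networks.yaml")
    with resources.as_file(ref) as path:
        return NetworkDefinition.from_yaml(path)
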