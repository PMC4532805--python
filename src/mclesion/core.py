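"""Shared constants and error types."""

from __future__ import annotations

#: Contrast identifiers, in canonical order. ``T2star`` is the T2* relaxation
#: time; T1/T2/T2star are in milliseconds, MTR is a dimensionless ratio.
CONTRASTS: tuple[str, ...] = ("T1", "T2", "T2star", "MTR")

#: Lobes used for the regional reference. ``cerebellum`` is treated as a
#: single lobe with its own WM/GM compartments.
LOBES: tuple[str, ...] = ("frontal", "parietal", "occipital", "temporal", "cerebellum")

TISSUES: tuple[str, ...] = ("WM", "GM")

#: Lesion tissue types: pure white matter, mixed GM/WM (cortical type I),
#: purely intracortical (cortical type II).
LESION_WM = "WM"
LESION_CORTICAL_I = "cortical-I"
LESION_CORTICAL_II = "cortical-II"
LESION_TYPES: tuple[str, ...] = (LESION_WM, LESION_CORTICAL_I, LESION_CORTICAL_II)


class ConfigurationError(ValueError):
    """A configuration is internally inconsistent or infeasible."""


class PlacementError(RuntimeError):
    """Requested lesions could not be placed without overlap."""


class MissingCompartmentError(KeyError):
    """A (lobe, tissue) compartment required for normalization is absent."""


class DegenerateReferenceError(ValueError):
    """A reference compartment has zero variance and cannot normalize."""


class OrphanLesionError(ValueError):
    """A lesion lies entirely on background atlas voxels."""
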