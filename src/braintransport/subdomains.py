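"""Subdomain label codes shared across the pipeline.

Integer codes are stable across NIfTI round trips; 0 is reserved for
voxels outside the brain.
"""

from __future__ import annotations

from enum import IntEnum


class Subdomain(IntEnum):
    """Per-voxel transport subdomain."""

    BACKGROUND = 0
    BT = 1          # brain tissue: interstitium + unresolved small PVS
    PAS_SURF = 2    # periarterial space of major surface arteries
    PAS_BRANCH = 3  # periarterial space of major branching arteries
    ARTERY = 4
    VENTRICLE = 5


#: Human-readable names keyed by integer code (for JSON sidecars).
LABEL_NAMES: dict[int, str] = {int(s): s.name for s in Subdomain}

#: Subdomains that carry a fitted effective diffusivity.
FITTED_SUBDOMAINS = (Subdomain.BT, Subdomain.PAS_SURF, Subdomain.PAS_BRANCH)

#: Subdomains whose diffusivity is tied to BT by the blocked fraction.
BLOCKED_SUBDOMAINS = (Subdomain.ARTERY, Subdomain.VENTRICLE)
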