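"""Shared identity types for gate-in-context devices.

A *gate-context* is the unit of characterization throughout the package:
one genetic inverter insert (a repressor plus its cognate promoter) carried
by one plasmid backbone inside one host strain. The same DNA insert in two
different contexts is treated as two distinct devices, because its
dose-response can differ qualitatively between them.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Plasmid backbones used in the study design; pAN is the E. coli vector,
#: the pSEVA series are broad-host-range vectors whose origin of
#: replication (RK2 / pBBR1 / RFS1010) sets the copy number.
BACKBONES = ("pAN", "pSEVA221", "pSEVA231", "pSEVA251")

#: Host strains: two Escherichia coli and one Pseudomonas putida.
HOSTS = ("EcDH5a", "EcCC118lpir", "PpKT2440")


def repressor_family(gate_name: str) -> str:
    """Family of the repressor in a gate, from the gate's name.

    Gate names follow the ``Family-V#`` convention (e.g. ``PhlF-P1`` and
    ``PhlF-P2`` are two promoter variants sharing the PhlF repressor), so
    the family is the prefix before the first dash.
    """
    return gate_name.split("-", 1)[0]


@dataclass(frozen=True, order=True)
class GateContext:
    """Identity of one gate-in-context device."""

    gate_name: str
    backbone: str
    host: str

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; expected one of {BACKBONES}")
        if self.host not in HOSTS:
            raise ValueError(f"unknown host {self.host!r}; expected one of {HOSTS}")

    @property
    def repressor_family(self) -> str:
        return repressor_family(self.gate_name)

    @property
    def label(self) -> str:
        return f"{self.host}({self.backbone}::{self.gate_name})"
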