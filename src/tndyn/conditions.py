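"""Condition labels shared across the pipeline.

A simulated or assayed condition is identified by genotype (WT or the DCM
mutant TnC G159D), phosphorylation state of cTnI (uP = unphosphorylated,
SEP = bis-phosphoserine mimic), and the ligand present.
"""

from __future__ import annotations

from dataclasses import dataclass

GENOTYPES = ("WT", "G159D")
PHOSPHO_STATES = ("uP", "SEP")


@dataclass(frozen=True)
class ConditionKey:
    genotype: str
    phospho: str
    ligand: str = "apo"

    def __post_init__(self) -> None:
        if not (self.genotype and self.phospho and self.ligand):
            raise ValueError("ConditionKey requires genotype, phospho and ligand")

    def tag(self) -> str:
        return f"{self.genotype}_{self.phospho}_{self.ligand}"

    def pair_key(self) -> tuple[str, str]:
        """(genotype, ligand): the axis along which phospho states are compared."""
        return (self.genotype, self.ligand)
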