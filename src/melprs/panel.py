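"""SNP panel: per-variant metadata for polygenic risk scoring.

A :class:`SnpPanel` holds, for each variant, the risk allele, a log-odds
weight, and the risk-allele frequency used for Hardy-Weinberg genotype
simulation and for mean-dosage imputation of missing genotypes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

_NUCLEOTIDES = "ACGT"


@dataclass(frozen=True)
class SnpRecord:
    """One panel variant.

    Parameters
    ----------
    snp_id:
        rs identifier (or any unique label).
    risk_allele:
        The allele whose dosage (0/1/2) enters the score.
    weight:
        Per-allele log odds ratio used in the weighted score.
    risk_allele_freq:
        Population frequency of the risk allele, strictly inside (0, 1).
    other_allele:
        The non-risk allele; defaults to the first nucleotide differing
        from the risk allele (only used when emitting VCF).
    gene:
        Optional gene / locus annotation.
    """

    snp_id: str
    risk_allele: str
    weight: float
    risk_allele_freq: float
    other_allele: str | None = None
    gene: str = ""

    def __post_init__(self) -> None:
        if self.risk_allele not in _NUCLEOTIDES:
            raise ValueError(
                f"{self.snp_id}: risk allele must be one of A/C/G/T, got {self.risk_allele!r}"
            )
        if not (0.0 < self.risk_allele_freq < 1.0):
            raise ValueError(
                f"{self.snp_id}: risk-allele frequency must be strictly in (0,1), "
                f"got {self.risk_allele_freq}"
            )
        if not math.isfinite(self.weight):
            raise ValueError(f"{self.snp_id}: weight must be finite")
        if self.other_allele is None:
            alt = next(a for a in _NUCLEOTIDES if a != self.risk_allele)
            object.__setattr__(self, "other_allele", alt)
        elif self.other_allele == self.risk_allele:
            raise ValueError(f"{self.snp_id}: other_allele equals risk allele")


@dataclass
class SnpPanel:
    """An ordered collection of :class:`SnpRecord` with unique ids."""

    records: list[SnpRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.snp_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("snp_id values must be unique within a panel")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, snp_id: str) -> SnpRecord:
        for r in self.records:
            if r.snp_id == snp_id:
                return r
        raise KeyError(snp_id)

    def __contains__(self, snp_id: str) -> bool:
        return any(r.snp_id == snp_id for r in self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    @property
    def weights(self) -> list[float]:
        return [r.weight for r in self.records]

    @property
    def freqs(self) -> list[float]:
        return [r.risk_allele_freq for r in self.records]

    def subset(self, snp_ids: Sequence[str]) -> "SnpPanel":
        return SnpPanel([self[s] for s in snp_ids])

    def with_weights(self, weights: Iterable[float]) -> "SnpPanel":
        """Return a copy with weights replaced (order-aligned)."""
        ws = list(weights)
        if len(ws) != len(self.records):
            raise ValueError("weight vector length does not match panel size")
        return SnpPanel(
            [
                SnpRecord(r.snp_id, r.risk_allele, w, r.risk_allele_freq, r.other_allele, r.gene)
                for r, w in zip(self.records, ws)
            ]
        )

    # -- serialisation ----------------------------------------------------

    def to_dicts(self) -> list[dict]:
        return [
            {
                "snp_id": r.snp_id,
                "risk_allele": r.risk_allele,
                "weight": r.weight,
                "risk_allele_freq": r.risk_allele_freq,
                "other_allele": r.other_allele,
                "gene": r.gene,
            }
            for r in self.records
        ]

    @classmethod
    def from_dicts(cls, rows: Iterable[dict]) -> "SnpPanel":
        return cls(
            [
                SnpRecord(
                    snp_id=str(d["snp_id"]),
                    risk_allele=str(d["risk_allele"]),
                    weight=float(d["weight"]),
                    risk_allele_freq=float(d["risk_allele_freq"]),
                    other_allele=d.get("other_allele"),
                    gene=str(d.get("gene", "")),
                )
                for d in rows
            ]
        )

    def save(self, path: str | Path) -> None:
        """Write the panel as YAML (``.yaml``/``.yml``) or JSON."""
        path = Path(path)
        data = {"panel": self.to_dicts()}
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SnpPanel":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
        return cls.from_dicts(data["panel"])


def default_panel() -> SnpPanel:
    """The 11-SNP melanoma susceptibility panel with default weights.

    Weights are the natural logs of the published pooled per-allele odds
    ratios (see :mod:`melprs.published`); frequencies are the published
    minor-allele frequencies, taken as risk-allele frequencies.  Both are
    overridable via :meth:`SnpPanel.with_weights` or a user panel file.
    """
    from .published import DEFAULT_PANEL_ROWS

    return SnpPanel.from_dicts(DEFAULT_PANEL_ROWS)
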