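"""Simulation configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Knobs for the synthetic genome / read / table generator.

    All counts are positive, rates live in [0, 1] and ``frag_len >=
    read_len``; :meth:`validate` enforces these.  The same seed yields
    byte-identical outputs.
    """

    seed: int = 0
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (5, 9)
    exon_len: tuple[int, int] = (150, 300)
    intron_len: tuple[int, int] = (2700, 3400)
    n_circ: int = 10
    circ_abundance: float = 30.0
    n_samples_per_condition: int = 3
    n_batches: int = 3
    nb_dispersion: float = 0.1
    planted_lfc: tuple[float, ...] | None = None  # per circRNA; None -> default plan
    read_len: int = 100
    frag_len: int = 250
    alu_len: int = 300
    editing_rate: float = 0.1
    transition_density: float = 5.0  # T-to-C per kb in bound flanks
    background_transition_density: float = 0.05
    adapter_frac: float = 0.05
    dup_frac: float = 0.05
    contam_frac: float = 0.02
    premrna_frac: float = 0.15
    gene_abundance: float = 300.0  # mean fragments per gene per sample
    batch_effect_sd: float = 0.1
    inverted_alu_circs: tuple[int, ...] | None = None  # None -> downregulated circs + 1 null
    n_background_alus: int = 12
    n_decoys: int = 2  # AT..AC decoy junctions
    decoy_pairs: int = 6  # read pairs per decoy per sample
    n_mirnas: int = 8
    mirna_len: int = 21
    adapter: str = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
    conditions: tuple[str, str] = ("WT", "MUT")

    # ------------------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return [
            f"{cond}_r{b + 1}"
            for cond in self.conditions
            for b in range(self.n_samples_per_condition)
        ]

    @property
    def design(self) -> dict[str, tuple[str, str]]:
        """sample -> (condition, batch).  Replicates pair up across
        conditions into batches, like repeated differentiation experiments."""
        out = {}
        for cond in self.conditions:
            for b in range(self.n_samples_per_condition):
                batch = f"exp{(b % self.n_batches) + 1}"
                out[f"{cond}_r{b + 1}"] = (cond, batch)
        return out

    def effective_lfc(self) -> tuple[float, ...]:
        if self.planted_lfc is not None:
            if len(self.planted_lfc) != self.n_circ:
                raise ConfigError("planted_lfc length must equal n_circ")
            return tuple(self.planted_lfc)
        # default plan: 40% down, 20% up, rest null
        n_down = max(1, int(round(self.n_circ * 0.4)))
        n_up = max(1, int(round(self.n_circ * 0.2)))
        lfc = [-2.0] * n_down + [2.0] * n_up + [0.0] * (self.n_circ - n_down - n_up)
        return tuple(lfc[: self.n_circ])

    def effective_inverted_alu_circs(self) -> tuple[int, ...]:
        if self.inverted_alu_circs is not None:
            return self.inverted_alu_circs
        lfc = self.effective_lfc()
        down = [i for i, x in enumerate(lfc) if x < 0]
        null = [i for i, x in enumerate(lfc) if x == 0]
        return tuple(down + null[-1:])

    # ------------------------------------------------------------------
    def validate(self) -> None:
        for name in (
            "n_genes",
            "n_circ",
            "n_samples_per_condition",
            "n_batches",
            "read_len",
            "frag_len",
            "alu_len",
            "n_mirnas",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in (
            "editing_rate",
            "adapter_frac",
            "dup_frac",
            "contam_frac",
            "premrna_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.frag_len < self.read_len:
            raise ConfigError("frag_len must be >= read_len")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be non-negative")
        lo, hi = self.exons_per_gene
        if lo < 3:
            raise ConfigError("genes need >= 3 exons so internal exons exist")
        if lo > hi:
            raise ConfigError("exons_per_gene range inverted")
        if self.effective_inverted_alu_circs():
            if self.intron_len[0] < 2 * self.alu_len + 2000:
                raise ConfigError(
                    "introns too short to host inverted Alus: need "
                    f"intron_len >= {2 * self.alu_len + 2000}"
                )
        if self.n_genes < self.n_circ + self.n_decoys:
            raise ConfigError("n_genes must be >= n_circ + n_decoys")

    # ------------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("exons_per_gene", "exon_len", "intron_len", "planted_lfc",
                    "inverted_alu_circs", "conditions"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self) -> str:
        data = asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        return yaml.safe_dump(data, sort_keys=False)
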