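"""Run configuration: defaults, validation, TOML round-trip."""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

from .homology import ScoringScheme

__all__ = ["RunConfig"]

_LINKAGES = {"average", "complete", "single"}


@dataclass(frozen=True)
class RunConfig:
    """All tunables of the pipeline in one place.

    Input paths are optional: when absent, the pipeline runs on a seeded
    synthetic demo (genome, annotation, planted loci, diverged panel).
    ``mirna_evalue_cutoff`` is the relaxed acceptance threshold applied to
    queries shorter than ``mirna_length_cutoff`` (mature-miRNA scale), whose
    short perfect matches cannot reach strong expectation values.
    """

    gff: str | None = None
    loci: str | None = None
    queries: str | None = None
    genomes: dict[str, str] = field(default_factory=dict)
    utr_threshold: int = 2000
    bin_width: int = 500
    word_size: int = 19
    evalue_cutoff: float = 1e-3
    mirna_evalue_cutoff: float = 1e-1
    mirna_length_cutoff: int = 40
    linkage: str = "average"
    identity_threshold: float = 80.0
    seed: int = 0

    def validate(self) -> None:
        if self.utr_threshold <= 0:
            raise ValueError("utr_threshold must be positive")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.evalue_cutoff <= 0 or self.mirna_evalue_cutoff <= 0:
            raise ValueError("evalue cutoffs must be positive")
        if self.linkage not in _LINKAGES:
            raise ValueError(f"linkage must be one of {sorted(_LINKAGES)}")
        if not 0 <= self.identity_threshold <= 100:
            raise ValueError("identity_threshold must lie in [0, 100]")

    def scheme(self) -> ScoringScheme:
        return replace(
            ScoringScheme(),
            word_size=self.word_size,
            evalue_cutoff=self.evalue_cutoff,
        )

    def mirna_scheme(self) -> ScoringScheme:
        return replace(self.scheme(), evalue_cutoff=self.mirna_evalue_cutoff)

    def scheme_for(self, query_id: str, sequence: str) -> ScoringScheme:
        if len(sequence) < self.mirna_length_cutoff:
            return self.mirna_scheme()
        return self.scheme()

    @classmethod
    def from_toml(cls, path: "str | Path") -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_toml(self, path: "str | Path") -> None:
        lines: list[str] = []
        for key, value in asdict(self).items():
            if value is None:
                continue
            if isinstance(value, dict):
                if value:
                    lines.append(f"[{key}]")
                    for k, v in value.items():
                        lines.append(f'"{k}" = "{v}"')
                continue
            if isinstance(value, str):
                lines.append(f'{key} = "{value}"')
            elif isinstance(value, bool):
                lines.append(f"{key} = {str(value).lower()}")
            elif isinstance(value, float):
                lines.append(f"{key} = {value!r}")
            else:
                lines.append(f"{key} = {value}")
        # tables must come last in TOML; re-order
        scalars = [l for l in lines if not (l.startswith("[") or l.startswith('"'))]
        tables = [l for l in lines if l.startswith("[") or l.startswith('"')]
        Path(path).write_text("\n".join(scalars + tables) + "\n", encoding="utf-8")

    def digest(self) -> str:
        """Stable hash of the configuration (logged with every run)."""
        canon = repr(sorted(asdict(self).items(), key=lambda kv: kv[0]))
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
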