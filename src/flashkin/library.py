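"""Species library of first-flash kinetic parameters (FFKPs).

A :class:`SpeciesEntry` stores, per species, the mean and standard deviation
of the six FFKPs measured in a UBAT-class bathyphotometer:

=========  =====================================  ==================
symbol     meaning                                units
=========  =====================================  ==================
RT         rise time (onset to peak)              ms
DT         decay time (peak to detection floor)   ms
FD         flash duration (RT + DT)               ms
EF         e-folding time (peak to PI/e)          ms
PI         peak intensity                         photons s^-1
FF-MSL     photons emitted over the first flash   photons flash^-1
=========  =====================================  ==================

The built-in library covers five dinoflagellates, one ctenophore and one
larvacean, with intensities in radiometrically corrected units (the 2.5x
instrument-calibration factor already applied).

Several printed FF-MSL means exceed the hard per-flash bound
FF-MSL <= PI * FD / 1000 (a flash cannot emit more photons than its peak
rate sustained over its whole duration). Those entries are flagged
``feasibility_limited``: the printed mean is stored untouched, and the
simulator emits the brightest feasible flashes instead of silently rescaling
the published value.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

PARAMS = ("rt", "dt", "fd", "ef", "pi", "ffmsl")

#: canonical pretty names, used in tables and error messages
PARAM_LABELS = {
    "rt": "RT (ms)",
    "dt": "DT (ms)",
    "fd": "FD (ms)",
    "ef": "EF (ms)",
    "pi": "PI (photons/s)",
    "ffmsl": "FF-MSL (photons/flash)",
}


@dataclass(frozen=True)
class SpeciesEntry:
    """Per-species FFKP distribution moments plus taxonomy metadata."""

    species_name: str
    genus: str
    n_observed: int
    means: dict[str, float]
    sds: dict[str, float]
    distribution_family: str = "lognormal"
    feasibility_limited: bool = False

    def validate(self) -> None:
        if self.n_observed < 1:
            raise ValueError(f"{self.species_name}: n_observed must be >= 1")
        if self.distribution_family not in ("lognormal", "truncnorm"):
            raise ValueError(
                f"{self.species_name}: unknown family {self.distribution_family!r}"
            )
        for p in PARAMS:
            if p not in self.means or p not in self.sds:
                raise ValueError(f"{self.species_name}: missing parameter {p!r}")
            if not self.means[p] > 0:
                raise ValueError(f"{self.species_name}: mean {p} must be > 0")
            if self.sds[p] < 0:
                raise ValueError(f"{self.species_name}: sd {p} must be >= 0")
        if self.means["fd"] < self.means["rt"]:
            raise ValueError(f"{self.species_name}: mean FD < mean RT")
        if self.means["ef"] > self.means["dt"]:
            raise ValueError(f"{self.species_name}: mean EF > mean DT")

    @property
    def ffmsl_feasible_mean(self) -> float:
        """Upper bound on an achievable FF-MSL mean: E[PI] * E[FD] / 1000."""
        return self.means["pi"] * self.means["fd"] / 1000.0


@dataclass
class SpeciesLibrary:
    """Ordered collection of :class:`SpeciesEntry`, unique by species name."""

    entries: list[SpeciesEntry]
    version: str = "0"
    provenance: str = ""

    def __post_init__(self) -> None:
        names = [e.species_name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        for e in self.entries:
            e.validate()

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[SpeciesEntry]:
        return iter(self.entries)

    def __getitem__(self, species_name: str) -> SpeciesEntry:
        for e in self.entries:
            if e.species_name == species_name:
                return e
        raise KeyError(species_name)

    @property
    def species(self) -> list[str]:
        return [e.species_name for e in self.entries]

    @property
    def genus_map(self) -> dict[str, str]:
        return {e.species_name: e.genus for e in self.entries}

    def mean_table(self):
        """Species x FFKP DataFrame of the library means (raw units)."""
        import pandas as pd

        return pd.DataFrame(
            {p: [e.means[p] for e in self.entries] for p in PARAMS},
            index=self.species,
        )

    def save(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "provenance": self.provenance,
            "species": [
                {
                    "species": e.species_name,
                    "genus": e.genus,
                    "n": e.n_observed,
                    "family": e.distribution_family,
                    "feasibility_limited": e.feasibility_limited,
                    "params": {
                        p: {"mean": e.means[p], "sd": e.sds[p]} for p in PARAMS
                    },
                }
                for e in self.entries
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SpeciesLibrary":
        payload = json.loads(Path(path).read_text())
        entries = [
            SpeciesEntry(
                species_name=s["species"],
                genus=s["genus"],
                n_observed=s["n"],
                distribution_family=s.get("family", "lognormal"),
                feasibility_limited=s.get("feasibility_limited", False),
                means={p: s["params"][p]["mean"] for p in PARAMS},
                sds={p: s["params"][p]["sd"] for p in PARAMS},
            )
            for s in payload["species"]
        ]
        return cls(
            entries,
            version=payload.get("version", "0"),
            provenance=payload.get("provenance", ""),
        )


def _entry(name, genus, n, rt, dt, fd, ef, pi, ffmsl) -> SpeciesEntry:
    means = dict(rt=rt[0], dt=dt[0], fd=fd[0], ef=ef[0], pi=pi[0], ffmsl=ffmsl[0])
    sds = dict(rt=rt[1], dt=dt[1], fd=fd[1], ef=ef[1], pi=pi[1], ffmsl=ffmsl[1])
    limited = ffmsl[0] > pi[0] * fd[0] / 1000.0
    return SpeciesEntry(
        species_name=name,
        genus=genus,
        n_observed=n,
        means=means,
        sds=sds,
        feasibility_limited=limited,
    )


def default_library() -> SpeciesLibrary:
    """Built-in seven-species FFKP library (UBAT, calibrated units).

    Five dinoflagellates, the ctenophore *Mnemiopsis leidyi* and the
    larvacean *Oikopleura sp.*; tuples are (mean, sd).
    """
    entries = [
        _entry(
            "Pyrocystis fusiformis", "Pyrocystis", 56,
            rt=(76.8, 31.0), dt=(513.0, 328.0), fd=(536.0, 288.0),
            ef=(129.0, 47.5), pi=(6.64e10, 4.48e10), ffmsl=(2.91e10, 1.79e10),
        ),
        _entry(
            "Pyrocystis noctiluca", "Pyrocystis", 53,
            rt=(65.0, 18.4), dt=(442.0, 211.0), fd=(515.0, 222.0),
            ef=(81.7, 27.2), pi=(1.80e10, 3.7e8), ffmsl=(8.82e9, 7.26e9),
        ),
        _entry(
            "Pyrodinium bahamense", "Pyrodinium", 60,
            rt=(42.0, 13.9), dt=(109.0, 44.3), fd=(160.0, 49.3),
            ef=(49.9, 18.5), pi=(8.44e8, 3.71e8), ffmsl=(4.41e8, 6.06e7),
        ),
        _entry(
            "Lingulodinium polyedra", "Lingulodinium", 33,
            rt=(39.7, 18.9), dt=(87.0, 46.9), fd=(133.0, 53.6),
            ef=(37.6, 12.8), pi=(2.68e8, 1.08e8), ffmsl=(7.98e7, 5.21e7),
        ),
        _entry(
            "Alexandrium monilatum", "Alexandrium", 57,
            rt=(52.0, 19.0), dt=(148.0, 57.7), fd=(208.0, 66.5),
            ef=(68.2, 19.3), pi=(1.12e9, 8.66e8), ffmsl=(5.51e8, 4.39e8),
        ),
        _entry(
            "Mnemiopsis leidyi", "Mnemiopsis", 52,
            rt=(215.0, 96.0), dt=(1.04e3, 393.0), fd=(1.24e3, 397.0),
            ef=(262.0, 67.6), pi=(1.60e12, 8.71e11), ffmsl=(8.10e11, 4.31e11),
        ),
        _entry(
            "Oikopleura sp.", "Oikopleura", 9,
            rt=(44.1, 16.9), dt=(162.0, 173.0), fd=(212.0, 195.0),
            ef=(70.4, 56.3), pi=(1.41e9, 7.72e8), ffmsl=(6.30e8, 4.89e8),
        ),
    ]
    return SpeciesLibrary(
        entries,
        version="1",
        provenance="built-in single-organism UBAT reference measurements",
    )


#: abbreviations used in figures/tables throughout the field
ABBREVIATIONS = {
    "Pyrodinium bahamense": "baha",
    "Lingulodinium polyedra": "poly",
    "Alexandrium monilatum": "moni",
    "Pyrocystis noctiluca": "nocti",
    "Pyrocystis fusiformis": "fusi",
    "Mnemiopsis leidyi": "leidyi",
    "Oikopleura sp.": "oiko",
}
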