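"""Sample sheets: sample -> breed -> geographic region.

The sharing rules downstream (>= 2 individuals per breed; every animal of a
region) are driven entirely by this mapping, so its invariants are enforced
strictly: unique sample ids, each breed in exactly one region, and region
labels drawn from the closed three-way set used in the study design.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

REGIONS = ("America", "AsiaOceania", "Europe")

__all__ = ["REGIONS", "SampleSheet", "read_sample_sheet"]


@dataclass(frozen=True)
class SampleSheet:
    entries: tuple[tuple[str, str, str], ...]  # (sample_id, breed, region)

    def __post_init__(self) -> None:
        ids = [s for s, _, _ in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dup}")
        breed_region: dict[str, str] = {}
        for _, breed, region in self.entries:
            if region not in REGIONS:
                raise ValueError(
                    f"unknown region {region!r}; expected one of {REGIONS}"
                )
            if breed_region.setdefault(breed, region) != region:
                raise ValueError(f"breed {breed!r} mapped to two regions")

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(s for s, _, _ in self.entries)

    @property
    def breeds(self) -> tuple[str, ...]:
        seen: list[str] = []
        for _, b, _ in self.entries:
            if b not in seen:
                seen.append(b)
        return tuple(seen)

    @property
    def regions(self) -> tuple[str, ...]:
        present = {r for _, _, r in self.entries}
        return tuple(r for r in REGIONS if r in present)

    def breed_of(self, sample_id: str) -> str:
        for s, b, _ in self.entries:
            if s == sample_id:
                return b
        raise KeyError(sample_id)

    def region_of(self, sample_id: str) -> str:
        for s, _, r in self.entries:
            if s == sample_id:
                return r
        raise KeyError(sample_id)

    def samples_of_breed(self, breed: str) -> tuple[str, ...]:
        return tuple(s for s, b, _ in self.entries if b == breed)

    def samples_of_region(self, region: str) -> tuple[str, ...]:
        return tuple(s for s, _, r in self.entries if r == region)

    def breeds_of_region(self, region: str) -> tuple[str, ...]:
        seen: list[str] = []
        for _, b, r in self.entries:
            if r == region and b not in seen:
                seen.append(b)
        return tuple(seen)

    def counts(self) -> pd.DataFrame:
        """Per-breed sample counts with the breed's region."""
        df = self.to_frame()
        return (
            df.groupby(["region", "breed"], sort=True)
            .size()
            .rename("n_samples")
            .reset_index()
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["sample", "breed", "region"])


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a delimited sheet with ``sample``, ``breed``, ``region`` columns."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = {"sample", "breed", "region"} - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet {path}: missing columns {sorted(missing)}")
    entries = tuple(
        (str(r.sample).strip(), str(r.breed).strip(), str(r.region).strip())
        for r in df.itertuples()
    )
    return SampleSheet(entries)
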