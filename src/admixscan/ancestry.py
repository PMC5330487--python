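"""Local-ancestry containers, global ancestry, and quartile ancestry contrasts."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Integer codes used for ancestral populations throughout the package.
NAM, EUR, AFR = 0, 1, 2
ANCESTRY_NAMES = ("NAM", "EUR", "AFR")


@dataclass
class AncestryMatrix:
    """Per-individual, per-marker count of Native American allele copies.

    Parameters
    ----------
    ids
        Individual identifiers, length ``n``.
    markers
        Marker map with columns ``marker``, ``chrom``, ``pos`` (1-based)
        and optionally ``cm`` (genetic position).
    nam
        ``(n, M)`` integer matrix of NAM copies in {0, 1, 2}.
    eur, afr
        Optional companion matrices for the other ancestries. When all
        three are present they sum to 2 everywhere.
    haplotypes
        Optional ``(n, 2, M)`` truth matrix of per-haplotype ancestry
        codes (0=NAM, 1=EUR, 2=AFR), retained by the simulator.
    """

    ids: np.ndarray
    markers: pd.DataFrame
    nam: np.ndarray
    eur: np.ndarray | None = None
    afr: np.ndarray | None = None
    haplotypes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.nam = np.asarray(self.nam)
        if self.nam.ndim != 2:
            raise ValueError("nam must be a 2-D (individuals x markers) matrix")
        if self.nam.shape != (len(self.ids), len(self.markers)):
            raise ValueError(
                f"nam shape {self.nam.shape} inconsistent with "
                f"{len(self.ids)} ids and {len(self.markers)} markers"
            )
        vals = np.unique(self.nam[~np.isnan(self.nam.astype(float))])
        if not np.isin(vals, [0, 1, 2]).all():
            raise ValueError("ancestry copy counts must be in {0, 1, 2}")
        if self.eur is not None and self.afr is not None:
            total = self.nam + np.asarray(self.eur) + np.asarray(self.afr)
            if not (total == 2).all():
                raise ValueError("NAM+EUR+AFR copies must sum to 2 at every entry")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_markers(self, mask: np.ndarray) -> "AncestryMatrix":
        mask = np.asarray(mask)
        return AncestryMatrix(
            ids=self.ids,
            markers=self.markers.loc[mask].reset_index(drop=True),
            nam=self.nam[:, mask],
            eur=None if self.eur is None else self.eur[:, mask],
            afr=None if self.afr is None else self.afr[:, mask],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, :, mask],
        )


@dataclass
class GlobalAncestry:
    """Per-individual genome-average ancestry proportions (sum to 1)."""

    ids: np.ndarray
    m_nam: np.ndarray
    m_eur: np.ndarray
    m_afr: np.ndarray

    def __post_init__(self) -> None:
        total = self.m_nam + self.m_eur + self.m_afr
        if not np.allclose(total, 1.0, atol=1e-9):
            raise ValueError("per-individual ancestry proportions must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"iid": self.ids, "m_nam": self.m_nam, "m_eur": self.m_eur, "m_afr": self.m_afr}
        )


def global_ancestry_from_local(ancestry: AncestryMatrix) -> GlobalAncestry:
    """Average local ancestry into per-individual global proportions.

    ``m_NAM`` is the unweighted mean over markers of (NAM copies)/2; the
    EUR and AFR proportions come from companion matrices when present,
    otherwise EUR absorbs the remainder (AFR defaults to 0).
    """
    if ancestry.n_markers == 0:
        raise ValueError("cannot derive global ancestry from an empty marker set")
    m_nam = ancestry.nam.mean(axis=1) / 2.0
    if ancestry.afr is not None:
        m_afr = ancestry.afr.mean(axis=1) / 2.0
    else:
        m_afr = np.zeros_like(m_nam)
    if ancestry.eur is not None:
        m_eur = ancestry.eur.mean(axis=1) / 2.0
    else:
        m_eur = 1.0 - m_nam - m_afr
    return GlobalAncestry(ids=ancestry.ids, m_nam=m_nam, m_eur=m_eur, m_afr=m_afr)


def quartile_ancestry_contrast(
    ancestry: AncestryMatrix,
    trait: np.ndarray,
    region: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Top-vs-bottom trait-quartile difference in mean NAM proportion.

    For every marker (optionally restricted to ``region``, a 1-based
    inclusive base-pair interval), individuals are ranked on the trait
    (stable order breaks ties), the top and bottom quartiles of size
    ``floor(n/4)`` are formed, and the difference in mean NAM proportion
    (copies/2) between top and bottom is reported as a value in [-1, 1].

    Returns a frame with columns ``marker``, ``chrom``, ``pos``,
    ``contrast``.
    """
    trait = np.asarray(trait, dtype=float)
    if trait.shape[0] != ancestry.n_individuals:
        raise ValueError("trait length must match the number of individuals")
    if np.isnan(trait).any():
        raise ValueError("trait must be complete for included individuals")
    n = len(trait)
    q = n // 4
    if q < 2:
        raise ValueError("fewer than 8 individuals: quartiles degenerate")

    am = ancestry
    if region is not None:
        start, end = region
        mask = (am.markers["pos"] >= start) & (am.markers["pos"] <= end)
        am = am.subset_markers(mask.to_numpy())

    order = np.argsort(trait, kind="stable")
    bottom, top = order[:q], order[-q:]
    prop = am.nam / 2.0
    contrast = prop[top].mean(axis=0) - prop[bottom].mean(axis=0)
    return pd.DataFrame(
        {
            "marker": am.markers["marker"].to_numpy(),
            "chrom": am.markers["chrom"].to_numpy(),
            "pos": am.markers["pos"].to_numpy(),
            "contrast": contrast,
        }
    )


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse a ``chr:start-end`` region string (1-based inclusive)."""
    try:
        chrom, span = region.split(":")
        start_s, end_s = span.split("-")
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ValueError(f"malformed region string {region!r}; expected chr:start-end") from exc
    if start > end:
        raise ValueError(f"region start {start} exceeds end {end}")
    return chrom, start, end
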