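"""Strains x TE-loci presence/absence matrix with strain metadata."""

from __future__ import annotations

import pandas as pd


class PresenceMatrix:
    """Boolean strains x orthologous-insertion matrix.

    Rows are strains, columns are ortholog-group ids.  ``metadata``, if given,
    is indexed by strain id and may carry ``population``, ``continent`` and
    ``climate`` columns.
    """

    def __init__(self, data: pd.DataFrame, metadata: pd.DataFrame | None = None):
        self.data = data.astype(bool)
        if self.data.index.has_duplicates:
            raise ValueError("strain ids must be unique")
        if metadata is not None:
            missing = set(self.data.index) - set(metadata.index)
            if missing:
                raise ValueError(f"metadata missing strains: {sorted(missing)}")
        self.metadata = metadata

    @property
    def strains(self) -> list[str]:
        return list(self.data.index)

    @property
    def loci(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_strains(self) -> int:
        return self.data.shape[0]

    def counts(self) -> pd.Series:
        """Number of carrier strains per locus."""
        return self.data.sum(axis=0)

    def frequencies(self) -> pd.Series:
        """Population frequency (carriers / strains) per locus."""
        return self.data.mean(axis=0)

    def subset_strains(self, strains: list[str]) -> "PresenceMatrix":
        meta = None if self.metadata is None else self.metadata.loc[strains]
        return PresenceMatrix(self.data.loc[strains], meta)

    def to_tsv(self, path) -> None:
        out = self.data.astype(int)
        out.index.name = "strain"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, metadata: pd.DataFrame | None = None) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.astype(bool), metadata)
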