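"""Expression matrices with gene-role annotation.

The container every stage consumes: a samples x genes matrix of
normalised (log-scale, upstream) expression values together with a role
for each gene — ``mirna``, ``mrna``, or ``tf_mrna`` (an mRNA coding for a
transcription factor).  Differential-expression filtering is assumed to
have happened upstream; this package takes the matrix as given.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GENE_ROLES", "ExpressionMatrix", "read_expression", "read_roles"]

GENE_ROLES = ("mirna", "mrna", "tf_mrna")


@dataclass
class ExpressionMatrix:
    """Samples x genes expression values plus a gene -> role map.

    ``values`` rows are samples, columns are genes.  Invariants checked at
    construction: at least 3 samples, no missing values, every column has
    nonzero variance, and every gene has a known role.
    """

    values: pd.DataFrame
    roles: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.shape[0] < 3:
            raise ValueError(
                f"need at least 3 samples, got {self.values.shape[0]}"
            )
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise ValueError(f"missing values in columns {bad[:5]}")
        variances = self.values.var(axis=0, ddof=0)
        if (variances == 0).any():
            bad = variances.index[variances == 0].tolist()
            raise ValueError(f"zero-variance columns {bad[:5]}")
        missing_roles = [g for g in self.values.columns if g not in self.roles]
        if missing_roles:
            raise ValueError(f"genes without a role: {missing_roles[:5]}")
        bad_roles = sorted(
            {r for r in self.roles.values() if r not in GENE_ROLES}
        )
        if bad_roles:
            raise ValueError(
                f"unknown roles {bad_roles}; expected one of {GENE_ROLES}"
            )

    # -- views --------------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def mirnas(self) -> list[str]:
        return sorted(g for g in self.genes if self.roles[g] == "mirna")

    @property
    def mrnas(self) -> list[str]:
        """All mRNA genes — TF-coding mRNAs included (they are mRNAs too)."""
        return sorted(g for g in self.genes if self.roles[g] != "mirna")

    def column(self, gene: str) -> np.ndarray:
        return self.values[gene].to_numpy(dtype=float)

    def matrix(self, genes=None) -> np.ndarray:
        if genes is None:
            return self.values.to_numpy(dtype=float)
        return self.values[list(genes)].to_numpy(dtype=float)

    # -- io -----------------------------------------------------------------

    def to_tsv(self, expression_path, roles_path) -> None:
        self.values.to_csv(expression_path, sep="\t", index_label="sample_id")
        with open(roles_path, "w") as fh:
            fh.write("gene_id\trole\n")
            for g in self.genes:
                fh.write(f"{g}\t{self.roles[g]}\n")


def read_roles(path) -> dict[str, str]:
    """Read a two-column ``gene_id<TAB>role`` table (with header)."""
    roles = pd.read_csv(path, sep="\t", dtype=str)
    if roles.shape[1] < 2:
        raise ValueError(f"{path}: expected columns gene_id, role")
    col_gene, col_role = roles.columns[:2]
    return dict(zip(roles[col_gene].str.strip(), roles[col_role].str.strip()))


def read_expression(expression_path, roles_path) -> ExpressionMatrix:
    """Read an expression TSV (first row gene ids, first column sample ids)
    and its companion role table."""
    values = pd.read_csv(expression_path, sep="\t", index_col=0)
    values.columns = [str(c).strip() for c in values.columns]
    roles = read_roles(roles_path)
    return ExpressionMatrix(values=values.astype(float), roles=roles)
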