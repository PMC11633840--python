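"""Core data container for multilevel item-response data.

One row per lower-level unit: H binary items, a group identifier, optional
lower-level covariates (vary by unit) and higher-level covariates (constant
within group).  Units are stored sorted by group with contiguous internal
group indices 0..J-1; user-facing labels are preserved for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DataValidationError(ValueError):
    """Raised when input data violate the container invariants."""


@dataclass
class ItemResponseData:
    """Units x items binary responses with group structure and covariates.

    Parameters
    ----------
    items : (N, H) array of 0/1
        Binary item responses Y_ijh.  Missing values are rejected.
    group_id : (N,) array
        Group membership of each unit (any hashable labels).
    z_low : (N, p_L) array, optional
        Lower-level covariates Z^L_ij.
    z_high : (N, p_H) or (J, p_H) array, optional
        Higher-level covariates Z^H_j; if given per unit they must be
        constant within group.
    """

    items: np.ndarray
    group_id: np.ndarray
    z_low: np.ndarray | None = None
    z_high: np.ndarray | None = None

    # filled in __post_init__
    group_labels: np.ndarray = field(init=False)
    group_index: np.ndarray = field(init=False)
    group_sizes: np.ndarray = field(init=False)
    group_starts: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        items = np.asarray(self.items)
        if items.ndim != 2 or items.size == 0:
            raise DataValidationError("items must be a non-empty N x H matrix")
        if np.isnan(items.astype(float)).any():
            raise DataValidationError("missing item values are not supported")
        if not np.isin(items, (0, 1)).all():
            bad = np.where(~np.isin(items, (0, 1)).all(axis=1))[0]
            raise DataValidationError(
                f"non-binary item values in rows {bad[:10].tolist()}"
            )
        group_id = np.asarray(self.group_id)
        if group_id.shape != (items.shape[0],):
            raise DataValidationError("group_id length must match items rows")

        labels, inverse = np.unique(group_id, return_inverse=True)
        order = np.argsort(inverse, kind="stable")
        self.items = items[order].astype(np.int8)
        self.group_labels = labels
        self.group_index = inverse[order]
        self.group_sizes = np.bincount(self.group_index, minlength=len(labels))
        if (self.group_sizes == 0).any():
            raise DataValidationError("every group must contain at least one unit")
        self.group_starts = np.concatenate(([0], np.cumsum(self.group_sizes)[:-1]))

        if self.z_low is not None:
            zl = np.atleast_2d(np.asarray(self.z_low, dtype=float))
            if zl.shape[0] == 1 and items.shape[0] != 1:
                zl = zl.T
            if zl.shape[0] != items.shape[0]:
                raise DataValidationError("z_low must have one row per unit")
            if not np.isfinite(zl).all():
                raise DataValidationError("z_low contains non-finite values")
            self.z_low = zl[order]

        if self.z_high is not None:
            zh = np.atleast_2d(np.asarray(self.z_high, dtype=float))
            if zh.shape[0] == 1 and zh.size > 1 and items.shape[0] != 1:
                zh = zh.T
            if not np.isfinite(zh).all():
                raise DataValidationError("z_high contains non-finite values")
            if zh.shape[0] == items.shape[0]:
                zh_sorted = zh[order]
                per_group = zh_sorted[self.group_starts]
                if not np.array_equal(
                    np.repeat(per_group, self.group_sizes, axis=0), zh_sorted
                ):
                    raise DataValidationError(
                        "z_high must be constant within each group"
                    )
                self.z_high = per_group
            elif zh.shape[0] == len(labels):
                self.z_high = zh
            else:
                raise DataValidationError(
                    "z_high must have one row per unit or per group"
                )

    # ------------------------------------------------------------------
    @property
    def n_units(self) -> int:
        return self.items.shape[0]

    @property
    def n_items(self) -> int:
        return self.items.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @property
    def p_low(self) -> int:
        return 0 if self.z_low is None else self.z_low.shape[1]

    @property
    def p_high(self) -> int:
        return 0 if self.z_high is None else self.z_high.shape[1]

    def z_high_per_unit(self) -> np.ndarray:
        """Higher-level covariates broadcast to one row per unit (N, p_H)."""
        if self.z_high is None:
            return np.empty((self.n_units, 0))
        return np.repeat(self.z_high, self.group_sizes, axis=0)

    def z_low_matrix(self) -> np.ndarray:
        if self.z_low is None:
            return np.empty((self.n_units, 0))
        return self.z_low

    def group_reduce(self, values: np.ndarray, axis: int = 0) -> np.ndarray:
        """Sum unit-level `values` within groups along `axis` (length N)."""
        return np.add.reduceat(values, self.group_starts, axis=axis)
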