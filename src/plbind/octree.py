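"""Octree spatial index for fixed-radius neighbour queries over atom clouds."""

from __future__ import annotations

import numpy as np

__all__ = ["Octree", "build_octree"]


class _Node:
    __slots__ = ("center", "half", "indices", "children")

    def __init__(self, center: np.ndarray, half: float):
        self.center = center
        self.half = half
        self.indices: list[int] | None = []  # None once split
        self.children: list["_Node"] | None = None


class Octree:
    """Axis-aligned octree over a set of 3-D points.

    Points are stored in leaves holding at most ``leaf_capacity`` entries;
    a leaf splits into eight octants until ``max_depth`` is reached.
    Duplicate / near-coincident points are handled by the depth limit.
    """

    def __init__(self, points: np.ndarray, leaf_capacity: int = 8, max_depth: int = 12):
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if points.shape[0] == 0:
            raise ValueError("octree requires at least one point")
        if leaf_capacity < 1:
            raise ValueError("leaf_capacity must be >= 1")
        if not np.isfinite(points).all():
            raise ValueError("points must be finite")
        self.points = points
        self.leaf_capacity = leaf_capacity
        self.max_depth = max_depth
        lo = points.min(axis=0)
        hi = points.max(axis=0)
        center = (lo + hi) / 2.0
        # cubic root cell; epsilon so boundary points fall strictly inside
        half = float(max((hi - lo).max() / 2.0, 1e-9)) * (1.0 + 1e-9)
        self._root = _Node(center, half)
        for i in range(points.shape[0]):
            self._insert(self._root, i, 0)

    # -- construction ------------------------------------------------------

    def _insert(self, node: _Node, idx: int, depth: int) -> None:
        while node.indices is None:
            node = node.children[self._octant(node, self.points[idx])]
            depth += 1
        node.indices.append(idx)
        if len(node.indices) > self.leaf_capacity and depth < self.max_depth:
            self._split(node, depth)

    def _split(self, node: _Node, depth: int) -> None:
        q = node.half / 2.0
        node.children = [
            _Node(node.center + q * np.array([dx, dy, dz]), q)
            for dx in (-1.0, 1.0)
            for dy in (-1.0, 1.0)
            for dz in (-1.0, 1.0)
        ]
        pending, node.indices = node.indices, None
        for i in pending:
            child = node.children[self._octant(node, self.points[i])]
            child.indices.append(i)
            if len(child.indices) > self.leaf_capacity and depth + 1 < self.max_depth:
                self._split(child, depth + 1)

    @staticmethod
    def _octant(node: _Node, p: np.ndarray) -> int:
        return (
            (4 if p[0] >= node.center[0] else 0)
            + (2 if p[1] >= node.center[1] else 0)
            + (1 if p[2] >= node.center[2] else 0)
        )

    # -- queries -----------------------------------------------------------

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) corners of the root cell; covers every point."""
        return self._root.center - self._root.half, self._root.center + self._root.half

    def query_ball(self, center, radius: float) -> list[int]:
        """Indices of all points with Euclidean distance <= radius of center."""
        center = np.asarray(center, dtype=float)
        if center.shape != (3,):
            raise ValueError("query center must be a 3-vector")
        if radius < 0:
            raise ValueError("radius must be non-negative")
        out: list[int] = []
        r2 = radius * radius
        stack = [self._root]
        while stack:
            node = stack.pop()
            # prune cells whose closest face is beyond radius
            d = np.maximum(np.abs(center - node.center) - node.half, 0.0)
            if d @ d > r2:
                continue
            if node.indices is not None:
                for i in node.indices:
                    diff = self.points[i] - center
                    if diff @ diff <= r2:
                        out.append(i)
            else:
                stack.extend(node.children)
        out.sort()
        return out


def build_octree(points, leaf_capacity: int = 8, max_depth: int = 12) -> Octree:
    """Build an :class:`Octree` over an (N, 3) coordinate array."""
    return Octree(points, leaf_capacity=leaf_capacity, max_depth=max_depth)
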