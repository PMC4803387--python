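"""Deterministic generators for every input the pipeline consumes.

Everything is a pure function of (seed, parameters) and returns a manifest
holding the planted ground truth, so tests never download anything.
"""

from __future__ import annotations

import json

import numpy as np

from .profiles import AA_ORDER, LabeledDataset, ProfileMatrix

__all__ = [
    "GenerationError",
    "gen_complex",
    "gen_sequence_families",
    "gen_labeled_features",
    "gen_profile",
    "write_psiblast_pssm",
]


class GenerationError(RuntimeError):
    pass


def _pdb_line(rec, serial, name, resname, chain, resseq, xyz, element):
    name_field = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{rec:<6s}{serial:5d} {name_field} {resname:>3s} {chain}{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def gen_complex(
    seed: int,
    n_residues: int = 10,
    binding_positions: tuple[int, ...] = (3, 7),
    cutoff: float = 5.0,
    cutoff_margin: float = 0.5,
    covalent: str | None = None,  # None | "to_polymer" | "ligand_pair"
) -> tuple[str, dict]:
    """Toy protein-ligand complex in strict fixed-column PDB text.

    The polymer is a 5-bead-per-residue chain laid out so consecutive
    residues are far apart; one ligand atom sits exactly (cutoff - margin)
    from the CA of each planted binding position and > (cutoff + margin)
    from every atom of every other residue.  ``covalent`` plants an extra
    CONECT-bonded ligand for the exclusion rule.
    """
    if cutoff_margin <= 0:
        raise ValueError("cutoff_margin must be positive")
    if any(p < 1 or p > n_residues for p in binding_positions):
        raise ValueError("binding positions outside [1, n_residues]")
    rng = np.random.default_rng(seed)
    spacing = cutoff + cutoff_margin + 4.0
    # small seeded jitter exercises the parser's full coordinate precision
    jitter = rng.uniform(-0.05, 0.05, size=(n_residues, 3))

    res_names = ["ALA", "GLY", "SER", "LEU", "VAL", "THR", "CYS", "ASP", "LYS", "PHE"]
    offsets = {
        "N": np.array([-1.2, 0.8, 0.0]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([1.2, 0.8, 0.0]),
        "O": np.array([1.3, 0.9, 1.0]),
        "CB": np.array([0.0, -1.0, 1.0]),
    }

    lines = []
    serial = 0
    atoms = []  # (position, name, coords) for the brute-force manifest
    ca_coords = {}
    cb_serials = {}
    for i in range(1, n_residues + 1):
        base = np.array([(i - 1) * spacing, 0.0, 0.0]) + jitter[i - 1]
        resname = res_names[(i - 1) % len(res_names)]
        for name, off in offsets.items():
            if name == "CB" and resname == "GLY":
                continue
            serial += 1
            xyz = base + off
            lines.append(_pdb_line("ATOM", serial, name, resname, "A", i, xyz, name[0]))
            atoms.append((i, name, xyz))
            if name == "CA":
                ca_coords[i] = xyz
            if name == "CB":
                cb_serials[i] = serial

    lig_atoms = []
    for k, p in enumerate(sorted(binding_positions), start=1):
        serial += 1
        xyz = ca_coords[p] + np.array([0.0, cutoff - cutoff_margin, 0.0])
        lines.append(_pdb_line("HETATM", serial, f"C{k}", "LIG", "A", n_residues + 1, xyz, "C"))
        lig_atoms.append(xyz)

    conect = []
    if covalent == "to_polymer":
        # extra single-atom ligand bonded to residue 1's CB
        serial += 1
        xyz = ca_coords[1] + np.array([0.0, -1.0, 2.8])
        lines.append(_pdb_line("HETATM", serial, "S1", "CVL", "A", n_residues + 2, xyz, "S"))
        conect.append(f"CONECT{cb_serials[1]:5d}{serial:5d}")
    elif covalent == "ligand_pair":
        # two extra ligands bonded to each other, neither to the polymer
        far = np.array([-3.0 * spacing, 0.0, 0.0])
        serial += 1
        s_a = serial
        lines.append(_pdb_line("HETATM", serial, "C1", "CVA", "A", n_residues + 2, far, "C"))
        serial += 1
        lines.append(
            _pdb_line("HETATM", serial, "C1", "CVB", "A", n_residues + 3, far + [1.5, 0, 0], "C")
        )
        conect.append(f"CONECT{s_a:5d}{serial:5d}")
    elif covalent is not None:
        raise ValueError(f"unknown covalent mode {covalent!r}")

    lines.extend(conect)
    lines.append("END")

    # brute-force planted-truth audit
    min_dist = {}
    for pos, _name, xyz in atoms:
        for lxyz in lig_atoms:
            d = float(np.linalg.norm(xyz - lxyz))
            if pos not in min_dist or d < min_dist[pos]:
                min_dist[pos] = d
    planted = set(binding_positions)
    for pos, d in min_dist.items():
        ok = d <= cutoff - 1e-9 if pos in planted else d > cutoff + cutoff_margin
        if binding_positions and not ok:
            raise GenerationError(f"residue {pos}: planted geometry violated (d={d:.3f})")

    manifest = {
        "seed": seed,
        "n_residues": n_residues,
        "binding_positions": sorted(planted),
        "cutoff": cutoff,
        "cutoff_margin": cutoff_margin,
        "ligand_ccd": "LIG" if binding_positions else None,
        "covalent": covalent,
        "covalent_ccds": {"to_polymer": ["CVL"], "ligand_pair": ["CVA", "CVB"]}.get(covalent, []),
        "min_distances": {str(p): round(min_dist[p], 6) for p in sorted(min_dist)},
        "n_polymer_atoms": len(atoms),
        "n_ligand_atoms": len(lig_atoms),
    }
    return "\n".join(lines) + "\n", manifest


_AA = AA_ORDER  # 20 letters


def gen_sequence_families(
    seed: int,
    n_families: int = 3,
    members: int = 3,
    mutation_rate: float = 0.02,
    length: int = 80,
) -> tuple[str, dict]:
    """FASTA of random families: independent ancestors, per-site mutants."""
    rng = np.random.default_rng(seed)
    records = []
    assignment = {}
    ancestors = []
    for f in range(n_families):
        ancestor = "".join(_AA[i] for i in rng.integers(0, 20, size=length))
        ancestors.append(ancestor)
        for m in range(members):
            seq = list(ancestor)
            if m > 0:
                for i in range(length):
                    if rng.random() < mutation_rate:
                        choices = _AA.replace(seq[i], "")
                        seq[i] = choices[rng.integers(0, len(choices))]
            sid = f"fam{f}_m{m}"
            records.append((sid, "".join(seq)))
            assignment[sid] = f
    fasta = "".join(f">{sid}\n{seq}\n" for sid, seq in records)
    manifest = {
        "seed": seed,
        "n_families": n_families,
        "members": members,
        "mutation_rate": mutation_rate,
        "length": length,
        "family_of": assignment,
        "ancestors": ancestors,
    }
    return fasta, manifest


def gen_labeled_features(
    seed: int,
    n_pos: int = 100,
    n_neg: int = 100,
    w: int = 5,
    separation_sigma: float = 4.0,
) -> tuple[LabeledDataset, dict]:
    """Two Gaussian classes in w x 21 feature space.

    Class means sit ``separation_sigma`` unit standard deviations apart
    along a seeded random direction in the 20-score coordinates; spacer
    coordinates carry the all-interior window pattern (zeros).
    """
    if separation_sigma < 0:
        raise ValueError("separation_sigma must be >= 0")
    if w < 1 or w % 2 == 0:
        raise ValueError("w must be odd and >= 1")
    rng = np.random.default_rng(seed)
    dim = w * 21
    score_cols = np.array([c for c in range(dim) if c % 21 != 20])
    spacer_cols = np.array([c for c in range(dim) if c % 21 == 20])

    direction = rng.normal(size=score_cols.size)
    direction /= np.linalg.norm(direction)

    n = n_pos + n_neg
    X = np.zeros((n, dim))
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    noise = rng.normal(size=(n, score_cols.size))
    shift = direction * separation_sigma
    X[:, score_cols] = noise
    X[:n_pos, score_cols] += shift
    X[:, spacer_cols] = 0.0

    order = rng.permutation(n)
    X, y = X[order], y[order]
    meta = [(f"synth{seed}", i + 1) for i in range(n)]
    data = LabeledDataset(X=X, y=y, meta=meta, w=w)
    manifest = {
        "seed": seed,
        "n_pos": n_pos,
        "n_neg": n_neg,
        "w": w,
        "separation_sigma": separation_sigma,
        "direction": direction.tolist(),
    }
    return data, manifest


def gen_profile(seed: int, length: int, seq_id: str = "prof") -> ProfileMatrix:
    """Random small-integer log-odds profile, PSI-BLAST-like in range."""
    rng = np.random.default_rng(seed)
    scores = rng.integers(-8, 9, size=(length, 20)).astype(float)
    seq = "".join(_AA[i] for i in rng.integers(0, 20, size=length))
    return ProfileMatrix(seq_id=seq_id, scores=scores, sequence=seq)


def write_psiblast_pssm(profile: ProfileMatrix, with_percentages: bool = True) -> str:
    """Serialize a profile in the PSI-BLAST ``-out_ascii_pssm`` ASCII dialect."""
    rng = np.random.default_rng(0)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed percentages rounded down, information per position, and relative weight of gapless real matches to pseudocounts",
        "            " + "   ".join(AA_ORDER) + ("   " + "   ".join(AA_ORDER) if with_percentages else ""),
    ]
    seq = profile.sequence or "A" * len(profile)
    for i, row in enumerate(profile.scores, start=1):
        cells = "".join(f"{int(v):4d}" for v in row)
        if with_percentages:
            pct = "".join(f"{int(p):4d}" for p in rng.integers(0, 100, size=20))
            cells = cells + pct
        lines.append(f"{i:5d} {seq[i - 1]} {cells}  0.50 0.10")
    lines += ["", "                      K         Lambda", "Standard Ungapped    0.1337     0.3176", ""]
    return "\n".join(lines)


def save_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
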