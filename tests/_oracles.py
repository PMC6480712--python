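"""Independent reference implementations used only to check the package.

Each oracle deliberately takes a different computational route from the
implementation it validates: quaternion eigenvalue RMSD vs SVD Kabsch,
normal-vector atan2 dihedral vs the in-package plane construction, plain
double loops vs vectorized distance kernels.
"""

from __future__ import annotations

import numpy as np

COULOMB = 332.0636


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimal RMSD via the quaternion characteristic-polynomial route.

    Builds Horn's 4x4 key matrix from the correlation of the centered point
    sets; the largest eigenvalue lambda_max gives
    rmsd = sqrt((Ga + Gb - 2 lambda_max) / M).
    """
    a = mobile - mobile.mean(axis=0)
    b = reference - reference.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(key).max()
    ga = np.sum(a * a)
    gb = np.sum(b * b)
    val = max(0.0, (ga + gb - 2.0 * lam) / len(a))
    return float(np.sqrt(val))


def dihedral_oracle(p1, p2, p3, p4) -> float:
    """Torsion on [0, 360) via atan2((n1 x n2).b2_hat, n1.n2)."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2_hat = b2 / np.linalg.norm(b2)
    ang = np.degrees(np.arctan2(np.dot(np.cross(n1, n2), b2_hat),
                                np.dot(n1, n2)))
    return float(np.mod(ang, 360.0))


def brute_min_distance(group_a: np.ndarray, group_b: np.ndarray) -> float:
    best = np.inf
    for a in group_a:
        for b in group_b:
            best = min(best, float(np.linalg.norm(a - b)))
    return best


def brute_contact_residues(frame_xyz, ligand_idx, receptor_idx, res_keys,
                           cutoff: float) -> set:
    """Residue keys with any receptor-ligand pair strictly below cutoff."""
    hits = set()
    for i in receptor_idx:
        for j in ligand_idx:
            if np.linalg.norm(frame_xyz[i] - frame_xyz[j]) < cutoff:
                hits.add(res_keys[i])
                break
    return hits


def brute_interface_energy(xyz_a, xyz_b, sigma_a, eps_a, q_a,
                           sigma_b, eps_b, q_b, cutoff: float) -> float:
    """Plain double loop over inter-protomer pairs (LJ + Coulomb/eps(r)=4r)."""
    total = 0.0
    for i in range(len(xyz_a)):
        for j in range(len(xyz_b)):
            r = float(np.linalg.norm(xyz_a[i] - xyz_b[j]))
            if r >= cutoff:
                continue
            sig = 0.5 * (sigma_a[i] + sigma_b[j])
            eps = np.sqrt(eps_a[i] * eps_b[j])
            sr6 = (sig / r) ** 6
            total += 4.0 * eps * (sr6**2 - sr6)
            total += q_a[i] * q_b[j] * COULOMB / (4.0 * r * r)
    return total
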