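"""Compiled production kernel: cell-list/Verlet neighbour search, midpoint
Brownian-dynamics stepping and in-loop condensin bond updates.

The numpy implementations in :mod:`chromodyn.forces`, :mod:`chromodyn.bonds`
and :mod:`chromodyn.integrate` define the semantics; this module reproduces
them at speed.  Equivalence is covered by tests (deterministic settings and
injected noise).

Layout notes
------------
* Positions are float64 ``(n, 3)``; trajectory frames are recorded float32.
* The repulsion neighbour search uses a hashed cell list rebuilt into a
  Verlet pair list (cutoff 15 nm + 4 nm skin); the list is refreshed when
  any bead has drifted half a skin since the last build.
* Bonds are site-local index pairs in fixed-capacity arrays; the cooldown
  arrays implement the re-formation window for freshly dissolved pairs.
* ``np.random`` inside the jitted code has its own MT19937 state, seeded at
  the top of every ``simulate_phase`` call, which makes runs reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["simulate_phase", "build_pairs_reference"]

_H1, _H2, _H3 = 73856093, 19349663, 83492791


@njit(cache=True, fastmath=True)
def _build_pairs(pos, rlist, count, order, pair_i, pair_j):
    """Hashed cell list -> pair list within rlist. Returns pair count, -1 on overflow."""
    n = pos.shape[0]
    inv = 1.0 / rlist
    M = count.shape[0] - 1
    mask = M - 1
    for b in range(M + 1):
        count[b] = 0
    for i in range(n):
        ix = np.int64(np.floor(pos[i, 0] * inv))
        iy = np.int64(np.floor(pos[i, 1] * inv))
        iz = np.int64(np.floor(pos[i, 2] * inv))
        h = ((ix * _H1) ^ (iy * _H2) ^ (iz * _H3)) & mask
        count[h + 1] += 1
    for b in range(M):
        count[b + 1] += count[b]
    for i in range(n):
        ix = np.int64(np.floor(pos[i, 0] * inv))
        iy = np.int64(np.floor(pos[i, 1] * inv))
        iz = np.int64(np.floor(pos[i, 2] * inv))
        h = ((ix * _H1) ^ (iy * _H2) ^ (iz * _H3)) & mask
        order[count[h]] = i
        count[h] += 1
    npair = 0
    cap = pair_i.shape[0]
    r2 = rlist * rlist
    seen = np.empty(27, np.int64)
    for i in range(n):
        ix = np.int64(np.floor(pos[i, 0] * inv))
        iy = np.int64(np.floor(pos[i, 1] * inv))
        iz = np.int64(np.floor(pos[i, 2] * inv))
        nseen = 0
        for ddx in range(-1, 2):
            for ddy in range(-1, 2):
                for ddz in range(-1, 2):
                    h = (((ix + ddx) * _H1) ^ ((iy + ddy) * _H2)
                         ^ ((iz + ddz) * _H3)) & mask
                    # distinct neighbour cells can collide into one bucket;
                    # scan each bucket once per centre bead
                    dup = False
                    for s in range(nseen):
                        if seen[s] == h:
                            dup = True
                            break
                    if dup:
                        continue
                    seen[nseen] = h
                    nseen += 1
                    lo = count[h - 1] if h > 0 else 0
                    hi = count[h]
                    for k in range(lo, hi):
                        j = order[k]
                        if j <= i:
                            continue
                        dx = pos[j, 0] - pos[i, 0]
                        dy = pos[j, 1] - pos[i, 1]
                        dz = pos[j, 2] - pos[i, 2]
                        if dx * dx + dy * dy + dz * dz <= r2:
                            if npair >= cap:
                                return -1
                            pair_i[npair] = i
                            pair_j[npair] = j
                            npair += 1
    return npair


def build_pairs_reference(pos: np.ndarray, rlist: float):
    """All i<j pairs within ``rlist`` via the cell-list path (test hook)."""
    n = pos.shape[0]
    M = 64
    while M < 2 * n:
        M *= 2
    count = np.zeros(M + 1, np.int64)
    order = np.empty(n, np.int64)
    pair_i = np.empty(64 * n, np.int64)
    pair_j = np.empty(64 * n, np.int64)
    npair = _build_pairs(np.asarray(pos, float), rlist, count, order, pair_i, pair_j)
    if npair < 0:
        raise RuntimeError("pair list overflow")
    pairs = {(int(a), int(b)) for a, b in zip(pair_i[:npair], pair_j[:npair])}
    return pairs


@njit(cache=True, fastmath=True)
def _det_forces(pos, F, chain_id, Ks, c2, c3, c4, Kc, c5, rcap, rrep, diam,
                sites, bond_i, bond_j, nb, pair_i, pair_j, npair):
    n = pos.shape[0]
    for i in range(n):
        F[i, 0] = 0.0; F[i, 1] = 0.0; F[i, 2] = 0.0
    for i in range(n - 1):
        if chain_id[i] != chain_id[i + 1]:
            continue
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d > 1e-12:
            fmag = Ks * (d - c2) / d
            F[i, 0] += fmag * dx; F[i, 1] += fmag * dy; F[i, 2] += fmag * dz
            F[i + 1, 0] -= fmag * dx; F[i + 1, 1] -= fmag * dy; F[i + 1, 2] -= fmag * dz
    for i in range(n - 2):
        if chain_id[i] != chain_id[i + 2]:
            continue
        dx = pos[i + 2, 0] - pos[i, 0]
        dy = pos[i + 2, 1] - pos[i, 1]
        dz = pos[i + 2, 2] - pos[i, 2]
        F[i, 0] += c4 * dx; F[i, 1] += c4 * dy; F[i, 2] += c4 * dz
        F[i + 2, 0] -= c4 * dx; F[i + 2, 1] -= c4 * dy; F[i + 2, 2] -= c4 * dz
    for k in range(npair):
        i = pair_i[k]; j = pair_j[k]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > rrep * rrep or d2 < 1e-24:
            continue
        d = np.sqrt(d2)
        if d < diam:
            mag = c3
        else:
            s = d / diam
            s2 = s * s
            s4 = s2 * s2
            mag = c3 / (s4 * s4 * s4)
        fmag = mag / d
        F[i, 0] -= fmag * dx; F[i, 1] -= fmag * dy; F[i, 2] -= fmag * dz
        F[j, 0] += fmag * dx; F[j, 1] += fmag * dy; F[j, 2] += fmag * dz
    for b in range(nb):
        si = sites[bond_i[b]]
        sj = sites[bond_j[b]]
        dx = pos[sj, 0] - pos[si, 0]
        dy = pos[sj, 1] - pos[si, 1]
        dz = pos[sj, 2] - pos[si, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d > rcap or d < 1e-12:
            continue
        fmag = Kc * (d - c5) / d
        F[si, 0] += fmag * dx; F[si, 1] += fmag * dy; F[si, 2] += fmag * dz
        F[sj, 0] -= fmag * dx; F[sj, 1] -= fmag * dy; F[sj, 2] -= fmag * dz


@njit(cache=True)
def _update_bonds(pos, sites, deg_cap, p_step, window, rcap,
                  bond_i, bond_j, nb, cd_i, cd_j, cd_t, ncd):
    S = sites.shape[0]
    deg = np.zeros(S, np.int64)
    for b in range(nb):
        deg[bond_i[b]] += 1
        deg[bond_j[b]] += 1
    # dissociation
    b = 0
    while b < nb:
        if np.random.random() < p_step:
            i = bond_i[b]; j = bond_j[b]
            deg[i] -= 1; deg[j] -= 1
            if ncd < cd_i.shape[0] and window > 0:
                cd_i[ncd] = i; cd_j[ncd] = j; cd_t[ncd] = window
                ncd += 1
            nb -= 1
            bond_i[b] = bond_i[nb]; bond_j[b] = bond_j[nb]
        else:
            b += 1
    # re-formation window
    c = 0
    while c < ncd:
        i = cd_i[c]; j = cd_j[c]
        rebonded = False
        if deg[i] < deg_cap and deg[j] < deg_cap:
            dx = pos[sites[j], 0] - pos[sites[i], 0]
            dy = pos[sites[j], 1] - pos[sites[i], 1]
            dz = pos[sites[j], 2] - pos[sites[i], 2]
            if dx * dx + dy * dy + dz * dz <= rcap * rcap:
                bond_i[nb] = i; bond_j[nb] = j; nb += 1
                deg[i] += 1; deg[j] += 1
                rebonded = True
        if rebonded or cd_t[c] <= 1:
            ncd -= 1
            cd_i[c] = cd_i[ncd]; cd_j[c] = cd_j[ncd]; cd_t[c] = cd_t[ncd]
        else:
            cd_t[c] -= 1
            c += 1
    # formation: random traversal, uniform partner choice
    perm = np.random.permutation(S)
    cand = np.empty(S, np.int64)
    for k in range(S):
        i = perm[k]
        if deg[i] >= deg_cap:
            continue
        nc = 0
        for j in range(S):
            if j == i or deg[j] >= deg_cap:
                continue
            dup = False
            for b in range(nb):
                if (bond_i[b] == i and bond_j[b] == j) or \
                   (bond_i[b] == j and bond_j[b] == i):
                    dup = True
                    break
            if dup:
                continue
            dx = pos[sites[j], 0] - pos[sites[i], 0]
            dy = pos[sites[j], 1] - pos[sites[i], 1]
            dz = pos[sites[j], 2] - pos[sites[i], 2]
            if dx * dx + dy * dy + dz * dz <= rcap * rcap:
                cand[nc] = j
                nc += 1
        while deg[i] < deg_cap and nc > 0:
            pick = np.random.randint(nc)
            j = cand[pick]
            cand[pick] = cand[nc - 1]
            nc -= 1
            if deg[j] >= deg_cap:
                continue
            bond_i[nb] = i; bond_j[nb] = j; nb += 1
            deg[i] += 1; deg[j] += 1
    return nb, ncd


@njit(cache=True, fastmath=True)
def simulate_phase(pos, chain_id, n_steps, dt, c1, Ks, c2, c3, c4, Kc, c5,
                   rcap, rrep, diam, p_unit, sites, deg_cap, rebond_window,
                   bond_i, bond_j, nb, cd_i, cd_j, cd_t, ncd,
                   seed, rec_stride, cylinder_r, skin, noise):
    """Integrate ``n_steps`` midpoint Brownian-dynamics steps in place.

    Returns (frames, bond_rec, bond_counts, mean_tension, nb, ncd).
    ``noise`` may supply entropic kicks for the first ``noise.shape[0]``
    steps (testing); pass a (0, 0, 0) array for internal draws.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    F = np.empty((n, 3))
    ent = np.empty((n, 3))
    half = np.empty((n, 3))
    M = 64
    while M < 2 * n:
        M *= 2
    count = np.zeros(M + 1, np.int64)
    order = np.empty(n, np.int64)
    pcap = 64 * n
    pair_i = np.empty(pcap, np.int64)
    pair_j = np.empty(pcap, np.int64)
    rlist = rrep + skin
    npair = _build_pairs(pos, rlist, count, order, pair_i, pair_j)
    if npair < 0:
        raise RuntimeError("neighbour pair list overflow")
    ref = pos.copy()
    trig2 = (0.5 * skin) ** 2
    nrec = n_steps // rec_stride + 1
    rec = np.empty((nrec, n, 3), np.float32)
    rec[0] = pos.astype(np.float32)
    S = sites.shape[0]
    maxb = max(1, S * deg_cap // 2 + 1)
    bond_rec = np.full((nrec, maxb, 2), -1, np.int32)
    bond_counts = np.zeros(nrec, np.int64)
    for b in range(min(nb, maxb)):
        bond_rec[0, b, 0] = bond_i[b]
        bond_rec[0, b, 1] = bond_j[b]
    bond_counts[0] = nb
    tension_acc = 0.0
    tension_cnt = 0
    p_step = p_unit * dt
    kick = c1 * dt
    r = 0
    for step in range(n_steps):
        if S > 1:
            nb, ncd = _update_bonds(pos, sites, deg_cap, p_step, rebond_window,
                                    rcap, bond_i, bond_j, nb, cd_i, cd_j, cd_t, ncd)
        if step < noise.shape[0]:
            for i in range(n):
                ent[i, 0] = dt * noise[step, i, 0]
                ent[i, 1] = dt * noise[step, i, 1]
                ent[i, 2] = dt * noise[step, i, 2]
        else:
            for i in range(n):
                z = 2.0 * np.random.random() - 1.0
                phi = 6.283185307179586 * np.random.random()
                rxy = np.sqrt(1.0 - z * z)
                ent[i, 0] = kick * rxy * np.cos(phi)
                ent[i, 1] = kick * rxy * np.sin(phi)
                ent[i, 2] = kick * z
        _det_forces(pos, F, chain_id, Ks, c2, c3, c4, Kc, c5, rcap, rrep, diam,
                    sites, bond_i, bond_j, nb, pair_i, pair_j, npair)
        for i in range(n):
            half[i, 0] = pos[i, 0] + 0.5 * (dt * F[i, 0] + ent[i, 0])
            half[i, 1] = pos[i, 1] + 0.5 * (dt * F[i, 1] + ent[i, 1])
            half[i, 2] = pos[i, 2] + 0.5 * (dt * F[i, 2] + ent[i, 2])
        _det_forces(half, F, chain_id, Ks, c2, c3, c4, Kc, c5, rcap, rrep, diam,
                    sites, bond_i, bond_j, nb, pair_i, pair_j, npair)
        for i in range(n):
            pos[i, 0] += dt * F[i, 0] + ent[i, 0]
            pos[i, 1] += dt * F[i, 1] + ent[i, 1]
            pos[i, 2] += dt * F[i, 2] + ent[i, 2]
        if cylinder_r > 0.0:
            for i in range(n):
                rr = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2)
                if rr > cylinder_r:
                    f = cylinder_r / rr
                    pos[i, 0] *= f
                    pos[i, 1] *= f
        moved = False
        for i in range(n):
            dx = pos[i, 0] - ref[i, 0]
            dy = pos[i, 1] - ref[i, 1]
            dz = pos[i, 2] - ref[i, 2]
            if dx * dx + dy * dy + dz * dz > trig2:
                moved = True
                break
        if moved:
            npair = _build_pairs(pos, rlist, count, order, pair_i, pair_j)
            if npair < 0:
                raise RuntimeError("neighbour pair list overflow")
            for i in range(n):
                ref[i, 0] = pos[i, 0]
                ref[i, 1] = pos[i, 1]
                ref[i, 2] = pos[i, 2]
        if (step + 1) % rec_stride == 0:
            r += 1
            rec[r] = pos.astype(np.float32)
            for b in range(min(nb, maxb)):
                bond_rec[r, b, 0] = bond_i[b]
                bond_rec[r, b, 1] = bond_j[b]
            bond_counts[r] = nb
            for i in range(n - 1):
                if chain_id[i] != chain_id[i + 1]:
                    continue
                d = np.sqrt((pos[i + 1, 0] - pos[i, 0]) ** 2
                            + (pos[i + 1, 1] - pos[i, 1]) ** 2
                            + (pos[i + 1, 2] - pos[i, 2]) ** 2)
                tension_acc += abs(Ks * (d - c2))
                tension_cnt += 1
    mean_tension = tension_acc / tension_cnt if tension_cnt > 0 else 0.0
    return rec, bond_rec, bond_counts, mean_tension, nb, ncd
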