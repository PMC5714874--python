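"""Compiled inner loop of the agent-based receptor-ligand simulation.

One time step applies, to every molecule in a fresh random order:
a fixed-length diffusive move (3-D for soluble molecules, 2-D on the
cell sphere for membrane-anchored receptors) with push-back collision
response and boundary handling, an orientation resample for Y-shaped
receptors (acceptance-rejection against excluded volume), one
dissociation trial per occupied binding site, and binding trials for
every free ligand in point contact with a free binding sphere.

Interaction partners are found through Verlet neighbor lists rebuilt
from a linked-cell grid whenever any molecule has drifted close to half
the skin distance.  Receptors are treated as rigid complexes: their
collision set includes currently bound ligands, so neighbor reach radii
cover the whole complex.  Molecules teleported between rebuilds (outer
boundary re-insertion, ligand release) are tracked in a `recent` list
so grid queries stay exhaustive.

The per-agent logic is written inline in `run_core` rather than as
helper functions: numba passes array arguments by value (fat structs),
which costs several hundred ns per call -- more than the physics of an
average step.  Helpers are only used on rare events (collisions,
boundary crossings, binding commits).

Randomness comes from an inline xorshift128+ generator seeded via
splitmix64, giving platform-independent reproducibility.

Everything here is internal; the public surface is `rlbind.engine`.
"""

import numpy as np
from numba import njit

_BISECT_TOL = 1e-7  # µm, push-back contact-gap tolerance
_BISECT_MAX = 60
_DBL = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _next(st):
    """xorshift128+ step; returns a uint64."""
    s1 = st[0]
    s0 = st[1]
    st[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0 ^ (s0 >> np.uint64(26))
    st[1] = s1
    return s0 + s1


@njit(cache=True, inline="always")
def _rand(st):
    """Uniform double in [0, 1)."""
    return float(_next(st) >> np.uint64(11)) * _DBL


@njit(cache=True)
def _seed_state(seed, st):
    # splitmix64 expansion of a small integer seed
    x = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    for i in range(2):
        x += np.uint64(0x9E3779B97F4A7C15)
        z = x
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        st[i] = z ^ (z >> np.uint64(31))
    if st[0] == np.uint64(0) and st[1] == np.uint64(0):
        st[0] = np.uint64(1)


@njit(cache=True)
def _rand_quat(st, q):
    # 4 i.i.d. normals via Box-Muller, normalized: Haar-uniform rotation
    for i in range(2):
        u1 = _rand(st)
        while u1 <= 1e-300:
            u1 = _rand(st)
        u2 = _rand(st)
        m = np.sqrt(-2.0 * np.log(u1))
        q[2 * i] = m * np.cos(2.0 * np.pi * u2)
        q[2 * i + 1] = m * np.sin(2.0 * np.pi * u2)
    s = np.sqrt(q[0] * q[0] + q[1] * q[1] + q[2] * q[2] + q[3] * q[3])
    for i in range(4):
        q[i] /= s


@njit(cache=True)
def _quat_to_rot(q, R):
    w, x, y, z = q[0], q[1], q[2], q[3]
    R[0, 0] = 1.0 - 2.0 * (y * y + z * z)
    R[0, 1] = 2.0 * (x * y - w * z)
    R[0, 2] = 2.0 * (x * z + w * y)
    R[1, 0] = 2.0 * (x * y + w * z)
    R[1, 1] = 1.0 - 2.0 * (x * x + z * z)
    R[1, 2] = 2.0 * (y * z - w * x)
    R[2, 0] = 2.0 * (x * z - w * y)
    R[2, 1] = 2.0 * (y * z + w * x)
    R[2, 2] = 1.0 - 2.0 * (x * x + y * y)


@njit(cache=True)
def _mem_frame(anchor, R_cell, psi, R):
    """World rotation of a membrane-anchored receptor.

    Local +z maps to the outward surface normal; psi is the azimuth.
    """
    nx = anchor[0] / R_cell
    ny = anchor[1] / R_cell
    nz = anchor[2] / R_cell
    if abs(nx) <= abs(ny) and abs(nx) <= abs(nz):
        ax, ay, az = 1.0, 0.0, 0.0
    elif abs(ny) <= abs(nz):
        ax, ay, az = 0.0, 1.0, 0.0
    else:
        ax, ay, az = 0.0, 0.0, 1.0
    e1x = ay * nz - az * ny
    e1y = az * nx - ax * nz
    e1z = ax * ny - ay * nx
    n1 = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x /= n1
    e1y /= n1
    e1z /= n1
    e2x = ny * e1z - nz * e1y
    e2y = nz * e1x - nx * e1z
    e2z = nx * e1y - ny * e1x
    c = np.cos(psi)
    s = np.sin(psi)
    R[0, 0] = c * e1x + s * e2x
    R[1, 0] = c * e1y + s * e2y
    R[2, 0] = c * e1z + s * e2z
    R[0, 1] = -s * e1x + c * e2x
    R[1, 1] = -s * e1y + c * e2y
    R[2, 1] = -s * e1z + c * e2z
    R[0, 2] = nx
    R[1, 2] = ny
    R[2, 2] = nz


@njit(cache=True)
def _receptor_world(anchor, R, local_sites, local_colls, sites_out, colls_out):
    K = local_sites.shape[0]
    M = local_colls.shape[0]
    for k in range(K):
        for c in range(3):
            sites_out[k, c] = (anchor[c]
                               + R[c, 0] * local_sites[k, 0]
                               + R[c, 1] * local_sites[k, 1]
                               + R[c, 2] * local_sites[k, 2])
    for m in range(M):
        for c in range(3):
            colls_out[m, c] = (anchor[c]
                               + R[c, 0] * local_colls[m, 0]
                               + R[c, 1] * local_colls[m, 1]
                               + R[c, 2] * local_colls[m, 2])


@njit(cache=True, inline="always")
def _bound_lig_pos(site, R, bond_local, contact, out):
    for c in range(3):
        out[c] = site[c] + contact * (R[c, 0] * bond_local[0]
                                      + R[c, 1] * bond_local[1]
                                      + R[c, 2] * bond_local[2])


@njit(cache=True)
def _grid_bin(x, y, z, origin, cell_size, dim):
    cx = int((x - origin) / cell_size)
    cy = int((y - origin) / cell_size)
    cz = int((z - origin) / cell_size)
    if cx < 0:
        cx = 0
    if cy < 0:
        cy = 0
    if cz < 0:
        cz = 0
    if cx >= dim:
        cx = dim - 1
    if cy >= dim:
        cy = dim - 1
    if cz >= dim:
        cz = dim - 1
    return cx, cy, cz


@njit(cache=True)
def _build_lists(pos, reach, skin, nb, nbcnt, ref_pos, cell_head, cell_stamp,
                 nxt, stamp, dim, cell_size, origin, recent_cnt):
    """Full neighbor-list rebuild via the linked-cell grid.

    Returns False on capacity overflow.  Resets the teleport list.
    """
    N = pos.shape[0]
    for i in range(N):
        nbcnt[i] = 0
        for c in range(3):
            ref_pos[i, c] = pos[i, c]
    for i in range(N):
        cx, cy, cz = _grid_bin(pos[i, 0], pos[i, 1], pos[i, 2], origin,
                               cell_size, dim)
        cell = (cx * dim + cy) * dim + cz
        if cell_stamp[cell] != stamp:
            cell_stamp[cell] = stamp
            cell_head[cell] = -1
        nxt[i] = cell_head[cell]
        cell_head[cell] = i
    maxnb = nb.shape[1]
    for i in range(N):
        cx, cy, cz = _grid_bin(pos[i, 0], pos[i, 1], pos[i, 2], origin,
                               cell_size, dim)
        for x in range(max(0, cx - 1), min(dim, cx + 2)):
            for y in range(max(0, cy - 1), min(dim, cy + 2)):
                for z in range(max(0, cz - 1), min(dim, cz + 2)):
                    cell = (x * dim + y) * dim + z
                    if cell_stamp[cell] != stamp:
                        continue
                    j = cell_head[cell]
                    while j >= 0:
                        if j > i:
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            cut = reach[i] + reach[j] + skin
                            if dx * dx + dy * dy + dz * dz < cut * cut:
                                if nbcnt[i] >= maxnb or nbcnt[j] >= maxnb:
                                    return False
                                nb[i, nbcnt[i]] = j
                                nbcnt[i] += 1
                                nb[j, nbcnt[j]] = i
                                nbcnt[j] += 1
                        j = nxt[j]
    recent_cnt[0] = 0
    return True


@njit(cache=True)
def _relist(i, pos, reach, skin, nb, nbcnt, ref_pos, cell_head, cell_stamp,
            nxt, stamp, dim, cell_size, origin, recent, recent_cnt):
    """Refresh molecule i's neighbor list after a teleport.

    Candidates come from the (possibly stale) grid -- every molecule has
    drifted less than skin/2 since the grid was filled -- plus the
    `recent` teleport list.  Molecule i is registered as recent.  Also
    inserts i into new neighbors' lists (stale entries elsewhere are
    harmless: lists are supersets).  Returns False on overflow.
    """
    maxnb = nb.shape[1]
    nbcnt[i] = 0
    for c in range(3):
        ref_pos[i, c] = pos[i, c]
    cx, cy, cz = _grid_bin(pos[i, 0], pos[i, 1], pos[i, 2], origin,
                           cell_size, dim)
    # conservative extra margin: stale binning is off by at most skin/2,
    # and cell_size >= 2*max_reach + skin, so +-1 cells still suffice
    for x in range(max(0, cx - 1), min(dim, cx + 2)):
        for y in range(max(0, cy - 1), min(dim, cy + 2)):
            for z in range(max(0, cz - 1), min(dim, cz + 2)):
                cell = (x * dim + y) * dim + z
                if cell_stamp[cell] != stamp:
                    continue
                j = cell_head[cell]
                while j >= 0:
                    if j != i:
                        if not _relist_try(i, j, pos, reach, skin, nb, nbcnt):
                            return False
                    j = nxt[j]
    for a in range(recent_cnt[0]):
        j = recent[a]
        if j != i:
            if not _relist_try(i, j, pos, reach, skin, nb, nbcnt):
                return False
    if recent_cnt[0] >= recent.shape[0]:
        return False
    recent[recent_cnt[0]] = i
    recent_cnt[0] += 1
    return True


@njit(cache=True)
def _relist_try(i, j, pos, reach, skin, nb, nbcnt):
    maxnb = nb.shape[1]
    dx = pos[i, 0] - pos[j, 0]
    dy = pos[i, 1] - pos[j, 1]
    dz = pos[i, 2] - pos[j, 2]
    cut = reach[i] + reach[j] + skin
    if dx * dx + dy * dy + dz * dz < cut * cut:
        # j might already be listed (e.g. repeated teleports)
        for a in range(nbcnt[i]):
            if nb[i, a] == j:
                return True
        if nbcnt[i] >= maxnb:
            return False
        nb[i, nbcnt[i]] = j
        nbcnt[i] += 1
        present = False
        for a in range(nbcnt[j]):
            if nb[j, a] == i:
                present = True
                break
        if not present:
            if nbcnt[j] >= maxnb:
                return False
            nb[j, nbcnt[j]] = i
            nbcnt[j] += 1
    return True


@njit(cache=True)
def _sphere_set_vs_receptor(centers, radii, ncen, j, NR, coll_world,
                            coll_radii, site_occ, pos, r_L):
    """First-found overlap depth of a candidate sphere set vs receptor
    complex j (collision spheres plus currently bound ligands); 0 if
    none.  Early-exits on the first positive depth: callers use the
    result as an overlap predicate, not as an exact maximum."""
    M = coll_world.shape[1]
    for a in range(ncen):
        for m in range(M):
            dx = centers[a, 0] - coll_world[j, m, 0]
            dy = centers[a, 1] - coll_world[j, m, 1]
            dz = centers[a, 2] - coll_world[j, m, 2]
            rr = radii[a] + coll_radii[m]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < rr * rr:
                return rr - np.sqrt(d2)
    K = site_occ.shape[1]
    for k in range(K):
        lid = site_occ[j, k]
        if lid >= 0:
            for a in range(ncen):
                dx = centers[a, 0] - pos[NR + lid, 0]
                dy = centers[a, 1] - pos[NR + lid, 1]
                dz = centers[a, 2] - pos[NR + lid, 2]
                rr = radii[a] + r_L
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < rr * rr:
                    return rr - np.sqrt(d2)
    return 0.0


@njit(cache=True)
def _set_overlap_vs_neighbors(i, centers, radii, ncen, bc0, bc1, bc2, br,
                              reach, NR, pos, coll_world,
                              coll_radii, site_occ, lb_rec, r_L,
                              nb, nbcnt, skip_rec):
    """First-found overlap of a candidate sphere set (for molecule i) vs
    i's neighbors; `skip_rec` excludes the moving complex itself.
    (bc, br) is a bounding sphere of the candidate set, used to skip
    neighbors out of range.  Early-exits on the first positive depth
    (overlap predicate)."""
    for a in range(nbcnt[i]):
        j = nb[i, a]
        bx = bc0 - pos[j, 0]
        by = bc1 - pos[j, 1]
        bz = bc2 - pos[j, 2]
        bcut = br + reach[j]
        if bx * bx + by * by + bz * bz > bcut * bcut:
            continue
        if j < NR:
            if j == skip_rec:
                continue
            d = _sphere_set_vs_receptor(centers, radii, ncen, j, NR,
                                        coll_world, coll_radii, site_occ,
                                        pos, r_L)
            if d > 0.0:
                return d
        else:
            if lb_rec[j - NR] >= 0:
                continue  # bound ligands are covered via their receptor
            for b in range(ncen):
                dx = centers[b, 0] - pos[j, 0]
                dy = centers[b, 1] - pos[j, 1]
                dz = centers[b, 2] - pos[j, 2]
                rr = radii[b] + r_L
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < rr * rr:
                    return rr - np.sqrt(d2)
    return 0.0


@njit(cache=True)
def _receptor_candidate(i, anchor, mem, yshape, R_cell, psi_i, quat_i,
                        local_sites, local_colls, coll_radii, site_occ,
                        bond_local, contact, r_L, NR,
                        Rc, s_sites, s_colls, cbuf, crad):
    """Fill cbuf/crad with receptor i's full complex at a candidate pose;
    returns the number of spheres written."""
    if mem == 1:
        _mem_frame(anchor, R_cell, psi_i, Rc)
    elif yshape == 1:
        _quat_to_rot(quat_i, Rc)
    else:
        for a in range(3):
            for b in range(3):
                Rc[a, b] = 1.0 if a == b else 0.0
    _receptor_world(anchor, Rc, local_sites, local_colls, s_sites, s_colls)
    M = local_colls.shape[0]
    K = local_sites.shape[0]
    n = 0
    for m in range(M):
        for c in range(3):
            cbuf[n, c] = s_colls[m, c]
        crad[n] = coll_radii[m]
        n += 1
    for k in range(K):
        lid = site_occ[i, k]
        if lid >= 0:
            _bound_lig_pos(s_sites[k], Rc, bond_local[lid], contact, cbuf[n])
            crad[n] = r_L
            n += 1
    return n


@njit(cache=True)
def _commit_receptor_pose(i, anchor, NR, contact, r_L,
                          Rc, s_sites, s_colls,
                          pos, rot, site_world, coll_world, site_occ,
                          bond_local):
    K = site_world.shape[1]
    M = coll_world.shape[1]
    for c in range(3):
        pos[i, c] = anchor[c]
    for a in range(3):
        for b in range(3):
            rot[i, a, b] = Rc[a, b]
    for k in range(K):
        for c in range(3):
            site_world[i, k, c] = s_sites[k, c]
    for m in range(M):
        for c in range(3):
            coll_world[i, m, c] = s_colls[m, c]
    for k in range(K):
        lid = site_occ[i, k]
        if lid >= 0:
            _bound_lig_pos(site_world[i, k], Rc, bond_local[lid], contact,
                           pos[NR + lid])


@njit(cache=True)
def _commit_bind(idx, j, k, dist, dx, dy, dz, NR, contact, r_L,
                 pos, rot, site_world, coll_world, coll_radii, site_occ,
                 lb_rec, lb_site, bond_local, nb, nbcnt):
    """Snap ligand ``idx`` to point contact with site (j, k) and bind.

    Rejected (returns False) if the snapped position would overlap any
    third party or another sphere of receptor j.
    """
    li = idx - NR
    ux = dx / dist
    uy = dy / dist
    uz = dz / dist
    sx = site_world[j, k, 0] + contact * ux
    sy = site_world[j, k, 1] + contact * uy
    sz = site_world[j, k, 2] + contact * uz
    # vs receptor j's other spheres (site spheres lead the collision
    # layout, so sphere k is the one in exact point contact)
    M = coll_world.shape[1]
    for m in range(M):
        if m == k:
            continue
        ddx = sx - coll_world[j, m, 0]
        ddy = sy - coll_world[j, m, 1]
        ddz = sz - coll_world[j, m, 2]
        if (r_L + coll_radii[m]
                - np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)) > 1e-12:
            return False
    K = site_world.shape[1]
    for kk in range(K):
        lid = site_occ[j, kk]
        if lid >= 0:
            ddx = sx - pos[NR + lid, 0]
            ddy = sy - pos[NR + lid, 1]
            ddz = sz - pos[NR + lid, 2]
            if 2.0 * r_L - np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz) > 1e-12:
                return False
    for a in range(nbcnt[idx]):
        jj = nb[idx, a]
        if jj == j:
            continue
        if jj < NR:
            for m in range(M):
                ddx = sx - coll_world[jj, m, 0]
                ddy = sy - coll_world[jj, m, 1]
                ddz = sz - coll_world[jj, m, 2]
                if (r_L + coll_radii[m]
                        - np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)) > 1e-12:
                    return False
            for kk in range(K):
                lid = site_occ[jj, kk]
                if lid >= 0:
                    ddx = sx - pos[NR + lid, 0]
                    ddy = sy - pos[NR + lid, 1]
                    ddz = sz - pos[NR + lid, 2]
                    if (2.0 * r_L
                            - np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)) > 1e-12:
                        return False
        else:
            if lb_rec[jj - NR] >= 0:
                continue
            ddx = sx - pos[jj, 0]
            ddy = sy - pos[jj, 1]
            ddz = sz - pos[jj, 2]
            if 2.0 * r_L - np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz) > 1e-12:
                return False
    pos[idx, 0] = sx
    pos[idx, 1] = sy
    pos[idx, 2] = sz
    site_occ[j, k] = li
    lb_rec[li] = j
    lb_site[li] = k
    # contact direction in the receptor's local frame
    bond_local[li, 0] = rot[j, 0, 0] * ux + rot[j, 1, 0] * uy + rot[j, 2, 0] * uz
    bond_local[li, 1] = rot[j, 0, 1] * ux + rot[j, 1, 1] * uy + rot[j, 2, 1] * uz
    bond_local[li, 2] = rot[j, 0, 2] * ux + rot[j, 1, 2] * uy + rot[j, 2, 2] * uz
    return True


@njit(cache=True)
def _reinsert_ligand(idx, st, NR, R_env, r_L, pos, coll_world, coll_radii,
                     site_occ, lb_rec, reach, skin, nb, nbcnt, ref_pos,
                     cell_head, cell_stamp, nxt, stamp, dim, cell_size,
                     origin, recent, recent_cnt, lbuf, lrad):
    """Random-periodic outer boundary: fresh identity at a random
    boundary point, rejection-sampled to be overlap-free.

    Returns 0 on success, 1 on neighbor overflow, 2 on placement failure.
    """
    for _attempt in range(1000):
        z = 2.0 * _rand(st) - 1.0
        phi = 2.0 * np.pi * _rand(st)
        r = np.sqrt(max(0.0, 1.0 - z * z))
        lbuf[0, 0] = R_env * r * np.cos(phi)
        lbuf[0, 1] = R_env * r * np.sin(phi)
        lbuf[0, 2] = R_env * z
        if _point_free(idx, lbuf, lrad, NR, pos, coll_world, coll_radii,
                       site_occ, lb_rec, r_L, reach, skin, cell_head,
                       cell_stamp, nxt, stamp, dim, cell_size, origin,
                       recent, recent_cnt):
            for c in range(3):
                pos[idx, c] = lbuf[0, c]
            if not _relist(idx, pos, reach, skin, nb, nbcnt, ref_pos,
                           cell_head, cell_stamp, nxt, stamp, dim, cell_size,
                           origin, recent, recent_cnt):
                return 1
            return 0
    return 2


@njit(cache=True)
def _point_free(idx, lbuf, lrad, NR, pos, coll_world, coll_radii, site_occ,
                lb_rec, r_L, reach, skin, cell_head, cell_stamp, nxt, stamp,
                dim, cell_size, origin, recent, recent_cnt):
    """True if a ligand sphere at lbuf[0] overlaps nothing.

    Candidates from the stale grid (valid within skin/2 drift) plus the
    recent-teleport list.
    """
    cx, cy, cz = _grid_bin(lbuf[0, 0], lbuf[0, 1], lbuf[0, 2], origin,
                           cell_size, dim)
    for x in range(max(0, cx - 1), min(dim, cx + 2)):
        for y in range(max(0, cy - 1), min(dim, cy + 2)):
            for z in range(max(0, cz - 1), min(dim, cz + 2)):
                cell = (x * dim + y) * dim + z
                if cell_stamp[cell] != stamp:
                    continue
                j = cell_head[cell]
                while j >= 0:
                    if j != idx and _mol_hits_point(j, idx, lbuf, lrad, NR,
                                                   pos, coll_world,
                                                   coll_radii, site_occ,
                                                   lb_rec, r_L):
                        return False
                    j = nxt[j]
    for a in range(recent_cnt[0]):
        j = recent[a]
        if j != idx and _mol_hits_point(j, idx, lbuf, lrad, NR, pos,
                                        coll_world, coll_radii, site_occ,
                                        lb_rec, r_L):
            return False
    return True


@njit(cache=True)
def _mol_hits_point(j, idx, lbuf, lrad, NR, pos, coll_world, coll_radii,
                    site_occ, lb_rec, r_L):
    if j < NR:
        return _sphere_set_vs_receptor(lbuf, lrad, 1, j, NR, coll_world,
                                       coll_radii, site_occ, pos, r_L) > 0.0
    if lb_rec[j - NR] >= 0:
        return False  # covered via its receptor
    dx = lbuf[0, 0] - pos[j, 0]
    dy = lbuf[0, 1] - pos[j, 1]
    dz = lbuf[0, 2] - pos[j, 2]
    return lrad[0] + r_L - np.sqrt(dx * dx + dy * dy + dz * dz) > 0.0


@njit(cache=True)
def _reinsert_receptor(i, st, NR, mem, yshape, R_cell, R_env, contact, r_L,
                       local_sites, local_colls, coll_radii, pos, psi, quat,
                       rot, site_world, coll_world, site_occ, lb_rec, lb_site,
                       bond_local, reach, skin, nb, nbcnt, ref_pos,
                       cell_head, cell_stamp, nxt, stamp, dim, cell_size,
                       origin, recent, recent_cnt,
                       newq, Rc, s_sites, s_colls, cbuf, crad, anchor):
    """Random-periodic outer boundary for a soluble receptor/complex.

    The complex re-enters intact (binding state preserved) at a uniform
    random boundary point with a fresh random orientation.
    Returns 0 on success, 1 on neighbor overflow, 2 on failure.
    """
    K = site_occ.shape[1]
    for _attempt in range(1000):
        z = 2.0 * _rand(st) - 1.0
        phi = 2.0 * np.pi * _rand(st)
        r = np.sqrt(max(0.0, 1.0 - z * z))
        anchor[0] = R_env * r * np.cos(phi)
        anchor[1] = R_env * r * np.sin(phi)
        anchor[2] = R_env * z
        if yshape == 1:
            _rand_quat(st, newq)
        else:
            for c in range(4):
                newq[c] = quat[i, c]
        n = _receptor_candidate(i, anchor, mem, yshape, R_cell, psi[i], newq,
                                local_sites, local_colls, coll_radii,
                                site_occ, bond_local, contact, r_L, NR,
                                Rc, s_sites, s_colls, cbuf, crad)
        ok = True
        for b in range(n):
            lb1 = cbuf[b:b + 1]
            lr1 = crad[b:b + 1]
            if not _point_free(i, lb1, lr1, NR, pos, coll_world, coll_radii,
                               site_occ, lb_rec, r_L, reach, skin, cell_head,
                               cell_stamp, nxt, stamp, dim, cell_size,
                               origin, recent, recent_cnt):
                ok = False
                break
        if ok:
            if yshape == 1:
                for c in range(4):
                    quat[i, c] = newq[c]
            _commit_receptor_pose(i, anchor, NR, contact, r_L, Rc, s_sites,
                                  s_colls, pos, rot, site_world, coll_world,
                                  site_occ, bond_local)
            if not _relist(i, pos, reach, skin, nb, nbcnt, ref_pos,
                           cell_head, cell_stamp, nxt, stamp, dim, cell_size,
                           origin, recent, recent_cnt):
                return 1
            for k in range(K):
                lid = site_occ[i, k]
                if lid >= 0:
                    if not _relist(NR + lid, pos, reach, skin, nb, nbcnt,
                                   ref_pos, cell_head, cell_stamp, nxt,
                                   stamp, dim, cell_size, origin, recent,
                                   recent_cnt):
                        return 1
            return 0
    return 2


@njit(cache=True)
def _audit(NR, NL, pos, coll_world, coll_radii, site_occ, lb_rec, r_L):
    """Brute-force max collision overlap depth between distinct molecules
    (same-complex pairs excluded)."""
    depth = 0.0
    M = coll_world.shape[1]
    N = NR + NL
    for i in range(N):
        for j in range(i + 1, N):
            if i < NR and j < NR:
                for a in range(M):
                    for b in range(M):
                        dx = coll_world[i, a, 0] - coll_world[j, b, 0]
                        dy = coll_world[i, a, 1] - coll_world[j, b, 1]
                        dz = coll_world[i, a, 2] - coll_world[j, b, 2]
                        d = (coll_radii[a] + coll_radii[b]
                             - np.sqrt(dx * dx + dy * dy + dz * dz))
                        if d > depth:
                            depth = d
            elif i < NR <= j:
                if lb_rec[j - NR] == i:
                    continue  # bound pair: point contact by construction
                for a in range(M):
                    dx = coll_world[i, a, 0] - pos[j, 0]
                    dy = coll_world[i, a, 1] - pos[j, 1]
                    dz = coll_world[i, a, 2] - pos[j, 2]
                    d = (coll_radii[a] + r_L
                         - np.sqrt(dx * dx + dy * dy + dz * dz))
                    if d > depth:
                        depth = d
            else:
                li = i - NR
                lj = j - NR
                if lb_rec[li] >= 0 and lb_rec[li] == lb_rec[lj]:
                    continue  # two ligands on the same bivalent receptor
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                d = 2.0 * r_L - np.sqrt(dx * dx + dy * dy + dz * dz)
                if d > depth:
                    depth = d
    return depth


@njit(cache=True)
def run_core(
    NR, NL, mem, yshape, valency,
    n_steps, sample_every, dt, p_on, p_off, step_R, step_L,
    R_cell, R_env, r_bind, r_L, contact_tol,
    local_sites, local_colls, coll_radii,
    pos, psi, quat, rot, site_world, coll_world, site_occ,
    lb_rec, lb_site, bond_local,
    reach, skin, nb, nbcnt, ref_pos, cell_head, cell_stamp, nxt,
    dim, cell_size,
    seed, audit_every,
    out_complex, out_bound, stats,
):
    """Run the simulation; record counts every ``sample_every`` steps.

    ``stats``: [bind_events, unbind_events, reinsertions, rebuilds,
    max_audit_depth, error_flag].  error_flag: 1 = neighbor-list
    overflow, 2 = placement failure at the boundary.
    """
    st = np.empty(2, dtype=np.uint64)
    _seed_state(seed, st)
    N = NR + NL
    contact = r_bind + r_L
    shell = contact + contact_tol
    origin = -R_env - 1e-9
    max_step = max(step_R, step_L)
    # rebuild before any molecule can out-drift the skin margin
    drift_lim = 0.5 * skin - max_step
    drift_lim2 = drift_lim * drift_lim
    K = local_sites.shape[0]
    M = local_colls.shape[0]

    order = np.empty(N, dtype=np.int32)
    for i in range(N):
        order[i] = i
    d3 = np.empty(3)
    cand = np.empty(3)
    tmp3 = np.empty(3)
    anchor = np.empty(3)
    newq = np.empty(4)
    Rc = np.empty((3, 3))
    s_sites = np.empty((K, 3))
    s_colls = np.empty((M, 3))
    cbuf = np.empty((M + K, 3))
    crad = np.empty(M + K)
    lbuf = np.empty((1, 3))
    lrad = np.empty(1)
    lrad[0] = r_L
    recent = np.empty(256, dtype=np.int32)
    recent_cnt = np.zeros(1, dtype=np.int64)

    stamp = 1
    if not _build_lists(pos, reach, skin, nb, nbcnt, ref_pos, cell_head,
                        cell_stamp, nxt, stamp, dim, cell_size, origin,
                        recent_cnt):
        stats[5] = 1.0
        return
    stats[3] += 1.0

    sample_idx = 0
    nsmp = out_complex.shape[0]
    need_rebuild = False

    for step in range(n_steps + 1):
        # ---- record ----
        if step % sample_every == 0 and sample_idx < nsmp:
            ncplx = 0
            nbnd = 0
            for i in range(NR):
                occ = 0
                for k in range(K):
                    if site_occ[i, k] >= 0:
                        occ += 1
                if occ > 0:
                    ncplx += 1
                nbnd += occ
            out_complex[sample_idx] = ncplx
            out_bound[sample_idx] = nbnd
            sample_idx += 1
        if step == n_steps:
            break

        if audit_every > 0 and step % audit_every == 0:
            dep = _audit(NR, NL, pos, coll_world, coll_radii, site_occ,
                         lb_rec, r_L)
            if dep > stats[4]:
                stats[4] = dep

        # ---- fresh random permutation (Fisher-Yates) ----
        for i in range(N - 1, 0, -1):
            j = int(_next(st) % np.uint64(i + 1))
            t = order[i]
            order[i] = order[j]
            order[j] = t

        for oi in range(N):
            idx = order[oi]

            # =========================== LIGAND ===========================
            if idx >= NR:
                li = idx - NR
                if lb_rec[li] >= 0:
                    continue  # bound: moves rigidly with its receptor

                z = 2.0 * _rand(st) - 1.0
                phi = 2.0 * np.pi * _rand(st)
                rxy = np.sqrt(max(0.0, 1.0 - z * z))
                dx = step_L * rxy * np.cos(phi)
                dy = step_L * rxy * np.sin(phi)
                dz = step_L * z
                cx = pos[idx, 0] + dx
                cy = pos[idx, 1] + dy
                cz = pos[idx, 2] + dz
                rr = np.sqrt(cx * cx + cy * cy + cz * cz)

                if rr > R_env:
                    res = _reinsert_ligand(
                        idx, st, NR, R_env, r_L, pos, coll_world, coll_radii,
                        site_occ, lb_rec, reach, skin, nb, nbcnt, ref_pos,
                        cell_head, cell_stamp, nxt, stamp, dim, cell_size,
                        origin, recent, recent_cnt, lbuf, lrad)
                    if res != 0:
                        stats[5] = float(res)
                        return
                    stats[2] += 1.0
                    if recent_cnt[0] >= 200:
                        need_rebuild = True
                    continue

                if rr < R_cell:
                    scale = (2.0 * R_cell - rr) / rr
                    cx *= scale
                    cy *= scale
                    cz *= scale

                # inline overlap scan vs neighbors (squared distances;
                # stops at the first overlap found)
                depth = 0.0
                nbi = nbcnt[idx]
                for a in range(nbi):
                    j = nb[idx, a]
                    bx = cx - pos[j, 0]
                    by = cy - pos[j, 1]
                    bz = cz - pos[j, 2]
                    bcut = r_L + reach[j]
                    if bx * bx + by * by + bz * bz > bcut * bcut:
                        continue
                    if j < NR:
                        for m in range(M):
                            ddx = cx - coll_world[j, m, 0]
                            ddy = cy - coll_world[j, m, 1]
                            ddz = cz - coll_world[j, m, 2]
                            rr2 = r_L + coll_radii[m]
                            dd2 = ddx * ddx + ddy * ddy + ddz * ddz
                            if dd2 < rr2 * rr2:
                                depth = rr2 - np.sqrt(dd2)
                                break
                        if depth > 0.0:
                            break
                        for k in range(K):
                            lid = site_occ[j, k]
                            if lid >= 0:
                                ddx = cx - pos[NR + lid, 0]
                                ddy = cy - pos[NR + lid, 1]
                                ddz = cz - pos[NR + lid, 2]
                                rr2 = 2.0 * r_L
                                dd2 = ddx * ddx + ddy * ddy + ddz * ddz
                                if dd2 < rr2 * rr2:
                                    depth = rr2 - np.sqrt(dd2)
                                    break
                        if depth > 0.0:
                            break
                    else:
                        if lb_rec[j - NR] >= 0:
                            continue
                        rr2 = 2.0 * r_L
                        if bx * bx + by * by + bz * bz < rr2 * rr2:
                            depth = 1.0
                            break

                if depth > 0.0:
                    # push-back: bisect along the (folded) displacement
                    dx = cx - pos[idx, 0]
                    dy = cy - pos[idx, 1]
                    dz = cz - pos[idx, 2]
                    lo = 0.0
                    hi = 1.0
                    dnrm = np.sqrt(dx * dx + dy * dy + dz * dz)
                    nit = 0
                    while (hi - lo) * dnrm > _BISECT_TOL and nit < _BISECT_MAX:
                        nit += 1
                        midf = 0.5 * (lo + hi)
                        lbuf[0, 0] = pos[idx, 0] + midf * dx
                        lbuf[0, 1] = pos[idx, 1] + midf * dy
                        lbuf[0, 2] = pos[idx, 2] + midf * dz
                        d = _set_overlap_vs_neighbors(
                            idx, lbuf, lrad, 1, lbuf[0, 0], lbuf[0, 1],
                            lbuf[0, 2], r_L, reach, NR, pos, coll_world,
                            coll_radii, site_occ, lb_rec, r_L, nb, nbcnt, -1)
                        if d > 0.0:
                            hi = midf
                        else:
                            lo = midf
                    pos[idx, 0] += lo * dx
                    pos[idx, 1] += lo * dy
                    pos[idx, 2] += lo * dz
                else:
                    pos[idx, 0] = cx
                    pos[idx, 1] = cy
                    pos[idx, 2] = cz

                ddx = pos[idx, 0] - ref_pos[idx, 0]
                ddy = pos[idx, 1] - ref_pos[idx, 1]
                ddz = pos[idx, 2] - ref_pos[idx, 2]
                if ddx * ddx + ddy * ddy + ddz * ddz > drift_lim2:
                    need_rebuild = True

                # ---- binding attempts (ligand side) ----
                if p_on > 0.0:
                    for a in range(nbcnt[idx]):
                        j = nb[idx, a]
                        if j >= NR:
                            continue
                        if valency == 1:
                            occupied = False
                            for k in range(K):
                                if site_occ[j, k] >= 0:
                                    occupied = True
                                    break
                            if occupied:
                                continue
                        bound_now = False
                        for k in range(K):
                            if site_occ[j, k] >= 0:
                                continue
                            ddx = pos[idx, 0] - site_world[j, k, 0]
                            ddy = pos[idx, 1] - site_world[j, k, 1]
                            ddz = pos[idx, 2] - site_world[j, k, 2]
                            dist = np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
                            if dist > shell or dist <= 0.0:
                                continue
                            if _rand(st) >= p_on:
                                continue
                            if _commit_bind(idx, j, k, dist, ddx, ddy, ddz,
                                            NR, contact, r_L, pos, rot,
                                            site_world, coll_world,
                                            coll_radii, site_occ, lb_rec,
                                            lb_site, bond_local, nb, nbcnt):
                                stats[0] += 1.0
                                bound_now = True
                                break
                        if bound_now:
                            break
                continue

            # ========================== RECEPTOR ==========================
            i = idx
            if mem == 1:
                nx = pos[i, 0] / R_cell
                ny = pos[i, 1] / R_cell
                nz = pos[i, 2] / R_cell
                z = 2.0 * _rand(st) - 1.0
                phi = 2.0 * np.pi * _rand(st)
                rxy = np.sqrt(max(0.0, 1.0 - z * z))
                ux = rxy * np.cos(phi)
                uy = rxy * np.sin(phi)
                uz = z
                dot = ux * nx + uy * ny + uz * nz
                tx = ux - dot * nx
                ty = uy - dot * ny
                tz = uz - dot * nz
                tn = np.sqrt(tx * tx + ty * ty + tz * tz)
                if tn > 1e-12:
                    cand[0] = pos[i, 0] + step_R * tx / tn
                    cand[1] = pos[i, 1] + step_R * ty / tn
                    cand[2] = pos[i, 2] + step_R * tz / tn
                    cn = _norm3v(cand)
                    for c in range(3):
                        cand[c] *= R_cell / cn
                else:
                    for c in range(3):
                        cand[c] = pos[i, c]
            else:
                z = 2.0 * _rand(st) - 1.0
                phi = 2.0 * np.pi * _rand(st)
                rxy = np.sqrt(max(0.0, 1.0 - z * z))
                cand[0] = pos[i, 0] + step_R * rxy * np.cos(phi)
                cand[1] = pos[i, 1] + step_R * rxy * np.sin(phi)
                cand[2] = pos[i, 2] + step_R * z
                rr = _norm3v(cand)
                if rr > R_env:
                    res = _reinsert_receptor(
                        i, st, NR, mem, yshape, R_cell, R_env, contact, r_L,
                        local_sites, local_colls, coll_radii, pos, psi, quat,
                        rot, site_world, coll_world, site_occ, lb_rec,
                        lb_site, bond_local, reach, skin, nb, nbcnt, ref_pos,
                        cell_head, cell_stamp, nxt, stamp, dim, cell_size,
                        origin, recent, recent_cnt, newq, Rc, s_sites,
                        s_colls, cbuf, crad, anchor)
                    if res != 0:
                        stats[5] = float(res)
                        return
                    stats[2] += 1.0
                    if recent_cnt[0] >= 200:
                        need_rebuild = True
                    # dissociation still happens this step
                    if p_off > 0.0:
                        for k in range(K):
                            lid = site_occ[i, k]
                            if lid >= 0 and _rand(st) < p_off:
                                site_occ[i, k] = -1
                                lb_rec[lid] = -1
                                lb_site[lid] = -1
                                stats[1] += 1.0
                                if not _relist(NR + lid, pos, reach, skin,
                                               nb, nbcnt, ref_pos, cell_head,
                                               cell_stamp, nxt, stamp, dim,
                                               cell_size, origin, recent,
                                               recent_cnt):
                                    stats[5] = 1.0
                                    return
                                if recent_cnt[0] >= 200:
                                    need_rebuild = True
                    continue
                if rr < R_cell:
                    scale = (2.0 * R_cell - rr) / rr
                    for c in range(3):
                        cand[c] *= scale

            # fast path: plain spherical soluble receptor (identity
            # orientation; cargo, if any, translates rigidly)
            fast = (mem == 0 and yshape == 0)
            if fast:
                lid0 = site_occ[i, 0]
                cx = cand[0]
                cy = cand[1]
                cz = cand[2]
                # cargo ligand position at the candidate anchor
                gx = gy = gz = 0.0
                if lid0 >= 0:
                    gx = cx + contact * bond_local[lid0, 0]
                    gy = cy + contact * bond_local[lid0, 1]
                    gz = cz + contact * bond_local[lid0, 2]
                depth = 0.0
                for a in range(nbcnt[i]):
                    j = nb[i, a]
                    bx = cx - pos[j, 0]
                    by = cy - pos[j, 1]
                    bz = cz - pos[j, 2]
                    bcut = reach[i] + reach[j]
                    if bx * bx + by * by + bz * bz > bcut * bcut:
                        continue
                    if j < NR:
                        rr2 = 2.0 * r_bind
                        if bx * bx + by * by + bz * bz < rr2 * rr2:
                            depth = 1.0
                            break
                        lid = site_occ[j, 0]
                        if lid >= 0:
                            ddx = cx - pos[NR + lid, 0]
                            ddy = cy - pos[NR + lid, 1]
                            ddz = cz - pos[NR + lid, 2]
                            rr2 = r_bind + r_L
                            if ddx * ddx + ddy * ddy + ddz * ddz < rr2 * rr2:
                                depth = 1.0
                                break
                        if lid0 >= 0:
                            ddx = gx - coll_world[j, 0, 0]
                            ddy = gy - coll_world[j, 0, 1]
                            ddz = gz - coll_world[j, 0, 2]
                            rr2 = r_L + r_bind
                            if ddx * ddx + ddy * ddy + ddz * ddz < rr2 * rr2:
                                depth = 1.0
                                break
                            if lid >= 0:
                                ddx = gx - pos[NR + lid, 0]
                                ddy = gy - pos[NR + lid, 1]
                                ddz = gz - pos[NR + lid, 2]
                                rr2 = 2.0 * r_L
                                if (ddx * ddx + ddy * ddy + ddz * ddz
                                        < rr2 * rr2):
                                    depth = 1.0
                                    break
                    else:
                        if lb_rec[j - NR] >= 0:
                            continue
                        rr2 = r_bind + r_L
                        if bx * bx + by * by + bz * bz < rr2 * rr2:
                            depth = 1.0
                            break
                        if lid0 >= 0:
                            ddx = gx - pos[j, 0]
                            ddy = gy - pos[j, 1]
                            ddz = gz - pos[j, 2]
                            rr2 = 2.0 * r_L
                            if ddx * ddx + ddy * ddy + ddz * ddz < rr2 * rr2:
                                depth = 1.0
                                break
                if depth > 0.0:
                    dx = cand[0] - pos[i, 0]
                    dy = cand[1] - pos[i, 1]
                    dz = cand[2] - pos[i, 2]
                    ncarg = 1
                    crad[0] = r_bind
                    if lid0 >= 0:
                        ncarg = 2
                        crad[1] = r_L
                    lo = 0.0
                    hi = 1.0
                    dnrm = np.sqrt(dx * dx + dy * dy + dz * dz)
                    nit = 0
                    while (hi - lo) * dnrm > _BISECT_TOL and nit < _BISECT_MAX:
                        nit += 1
                        midf = 0.5 * (lo + hi)
                        cbuf[0, 0] = pos[i, 0] + midf * dx
                        cbuf[0, 1] = pos[i, 1] + midf * dy
                        cbuf[0, 2] = pos[i, 2] + midf * dz
                        if lid0 >= 0:
                            cbuf[1, 0] = cbuf[0, 0] + contact * bond_local[lid0, 0]
                            cbuf[1, 1] = cbuf[0, 1] + contact * bond_local[lid0, 1]
                            cbuf[1, 2] = cbuf[0, 2] + contact * bond_local[lid0, 2]
                        d = _set_overlap_vs_neighbors(
                            i, cbuf, crad, ncarg, cbuf[0, 0], cbuf[0, 1],
                            cbuf[0, 2], reach[i], reach, NR, pos, coll_world,
                            coll_radii, site_occ, lb_rec, r_L, nb, nbcnt, i)
                        if d > 0.0:
                            hi = midf
                        else:
                            lo = midf
                    cand[0] = pos[i, 0] + lo * dx
                    cand[1] = pos[i, 1] + lo * dy
                    cand[2] = pos[i, 2] + lo * dz
                for c in range(3):
                    pos[i, c] = cand[c]
                    site_world[i, 0, c] = cand[c]
                    coll_world[i, 0, c] = cand[c]
                if lid0 >= 0:
                    pos[NR + lid0, 0] = cand[0] + contact * bond_local[lid0, 0]
                    pos[NR + lid0, 1] = cand[1] + contact * bond_local[lid0, 1]
                    pos[NR + lid0, 2] = cand[2] + contact * bond_local[lid0, 2]
            else:
                # generic path: candidate pose, push-back by bisection
                n = _receptor_candidate(i, cand, mem, yshape, R_cell, psi[i],
                                        quat[i], local_sites, local_colls,
                                        coll_radii, site_occ, bond_local,
                                        contact, r_L, NR, Rc, s_sites,
                                        s_colls, cbuf, crad)
                depth = _set_overlap_vs_neighbors(
                    i, cbuf, crad, n, cand[0], cand[1], cand[2], reach[i],
                    reach, NR, pos, coll_world, coll_radii,
                    site_occ, lb_rec, r_L, nb, nbcnt, i)
                if depth > 0.0:
                    for c in range(3):
                        d3[c] = cand[c] - pos[i, c]
                    lo = 0.0
                    hi = 1.0
                    dnrm = np.sqrt(d3[0] * d3[0] + d3[1] * d3[1]
                                   + d3[2] * d3[2])
                    nit = 0
                    while (hi - lo) * dnrm > _BISECT_TOL and nit < _BISECT_MAX:
                        nit += 1
                        midf = 0.5 * (lo + hi)
                        for c in range(3):
                            tmp3[c] = pos[i, c] + midf * d3[c]
                        if mem == 1:
                            tn = _norm3v(tmp3)
                            for c in range(3):
                                tmp3[c] *= R_cell / tn
                        n = _receptor_candidate(
                            i, tmp3, mem, yshape, R_cell, psi[i], quat[i],
                            local_sites, local_colls, coll_radii, site_occ,
                            bond_local, contact, r_L, NR, Rc, s_sites,
                            s_colls, cbuf, crad)
                        d = _set_overlap_vs_neighbors(
                            i, cbuf, crad, n, tmp3[0], tmp3[1], tmp3[2],
                            reach[i], reach, NR, pos, coll_world,
                            coll_radii, site_occ, lb_rec, r_L, nb, nbcnt, i)
                        if d > 0.0:
                            hi = midf
                        else:
                            lo = midf
                    for c in range(3):
                        cand[c] = pos[i, c] + lo * d3[c]
                    if mem == 1:
                        tn = _norm3v(cand)
                        for c in range(3):
                            cand[c] *= R_cell / tn
                    _receptor_candidate(i, cand, mem, yshape, R_cell, psi[i],
                                        quat[i], local_sites, local_colls,
                                        coll_radii, site_occ, bond_local,
                                        contact, r_L, NR, Rc, s_sites,
                                        s_colls, cbuf, crad)
                _commit_receptor_pose(i, cand, NR, contact, r_L, Rc, s_sites,
                                      s_colls, pos, rot, site_world,
                                      coll_world, site_occ, bond_local)

                # orientation resample (Y-shaped receptors)
                if yshape == 1:
                    if mem == 1:
                        new_psi = 2.0 * np.pi * _rand(st)
                        n = _receptor_candidate(
                            i, pos[i], mem, yshape, R_cell, new_psi, quat[i],
                            local_sites, local_colls, coll_radii, site_occ,
                            bond_local, contact, r_L, NR, Rc, s_sites,
                            s_colls, cbuf, crad)
                    else:
                        _rand_quat(st, newq)
                        n = _receptor_candidate(
                            i, pos[i], mem, yshape, R_cell, psi[i], newq,
                            local_sites, local_colls, coll_radii, site_occ,
                            bond_local, contact, r_L, NR, Rc, s_sites,
                            s_colls, cbuf, crad)
                    d = _set_overlap_vs_neighbors(
                        i, cbuf, crad, n, pos[i, 0], pos[i, 1], pos[i, 2],
                        reach[i], reach, NR, pos, coll_world, coll_radii,
                        site_occ, lb_rec, r_L, nb, nbcnt, i)
                    if d <= 0.0:
                        if mem == 1:
                            psi[i] = new_psi
                        else:
                            for c in range(4):
                                quat[i, c] = newq[c]
                        for c in range(3):
                            anchor[c] = pos[i, c]
                        _commit_receptor_pose(i, anchor, NR, contact, r_L,
                                              Rc, s_sites, s_colls, pos, rot,
                                              site_world, coll_world,
                                              site_occ, bond_local)

            ddx = pos[i, 0] - ref_pos[i, 0]
            ddy = pos[i, 1] - ref_pos[i, 1]
            ddz = pos[i, 2] - ref_pos[i, 2]
            if ddx * ddx + ddy * ddy + ddz * ddz > drift_lim2:
                need_rebuild = True

            # ---- dissociation ----
            if p_off > 0.0:
                for k in range(K):
                    lid = site_occ[i, k]
                    if lid >= 0 and _rand(st) < p_off:
                        site_occ[i, k] = -1
                        lb_rec[lid] = -1
                        lb_site[lid] = -1
                        stats[1] += 1.0
                        # the released ligand moved with the receptor while
                        # bound; refresh its lists before it diffuses freely
                        if not _relist(NR + lid, pos, reach, skin, nb, nbcnt,
                                       ref_pos, cell_head, cell_stamp, nxt,
                                       stamp, dim, cell_size, origin, recent,
                                       recent_cnt):
                            stats[5] = 1.0
                            return
                        if recent_cnt[0] >= 200:
                            need_rebuild = True

            # ---- binding attempts (receptor side) ----
            if p_on > 0.0:
                for a in range(nbcnt[i]):
                    j = nb[i, a]
                    if j < NR:
                        continue
                    lj = j - NR
                    if lb_rec[lj] >= 0:
                        continue
                    if valency == 1:
                        occupied = False
                        for k in range(K):
                            if site_occ[i, k] >= 0:
                                occupied = True
                                break
                        if occupied:
                            break
                    got = False
                    for k in range(K):
                        if site_occ[i, k] >= 0:
                            continue
                        ddx = pos[j, 0] - site_world[i, k, 0]
                        ddy = pos[j, 1] - site_world[i, k, 1]
                        ddz = pos[j, 2] - site_world[i, k, 2]
                        dist = np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
                        if dist > shell or dist <= 0.0:
                            continue
                        if _rand(st) >= p_on:
                            continue
                        if _commit_bind(j, i, k, dist, ddx, ddy, ddz, NR,
                                        contact, r_L, pos, rot, site_world,
                                        coll_world, coll_radii, site_occ,
                                        lb_rec, lb_site, bond_local,
                                        nb, nbcnt):
                            stats[0] += 1.0
                            got = True
                            break
                    if got and valency == 1:
                        break

        # ---- end-of-step neighbor refresh ----
        if need_rebuild:
            stamp += 1
            if not _build_lists(pos, reach, skin, nb, nbcnt, ref_pos,
                                cell_head, cell_stamp, nxt, stamp, dim,
                                cell_size, origin, recent_cnt):
                stats[5] = 1.0
                return
            stats[3] += 1.0
            need_rebuild = False


@njit(cache=True, inline="always")
def _norm3v(v):
    return np.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
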