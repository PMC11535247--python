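"""Numba kernels for the Potts dynamics and diffusion solvers.

All kernels operate on the flat per-cell arrays owned by
``lattice.CellTable`` and on plain 3-D float/int grids; nothing here
touches Python objects.  Cell-type codes match ``lattice.CellType``.
"""

import numpy as np
from numba import njit

MEDIUM = 0
DONOR = 4

# ------------------------------------------------------------------ geometry


@njit(cache=False, inline="always")
def _max_eig_sym3(a00, a11, a22, a01, a02, a12):
    """Largest eigenvalue of a symmetric 3x3 matrix (trigonometric form)."""
    p1 = a01 * a01 + a02 * a02 + a12 * a12
    if p1 < 1e-30:
        m = a00
        if a11 > m:
            m = a11
        if a22 > m:
            m = a22
        return m
    q = (a00 + a11 + a22) / 3.0
    p2 = (a00 - q) ** 2 + (a11 - q) ** 2 + (a22 - q) ** 2 + 2.0 * p1
    p = np.sqrt(p2 / 6.0)
    b00 = (a00 - q) / p
    b11 = (a11 - q) / p
    b22 = (a22 - q) / p
    b01 = a01 / p
    b02 = a02 / p
    b12 = a12 / p
    detb = (b00 * (b11 * b22 - b12 * b12)
            - b01 * (b01 * b22 - b12 * b02)
            + b02 * (b01 * b12 - b11 * b02))
    r = detb / 2.0
    if r < -1.0:
        r = -1.0
    elif r > 1.0:
        r = 1.0
    phi = np.arccos(r) / 3.0
    return q + 2.0 * p * np.cos(phi)


@njit(cache=False, inline="always")
def _axis_from_sums(n, s0, s1, s2, s3, s4, s5, s6, s7, s8):
    """Major-axis length from raw moment sums; +1/12 voxel self-variance."""
    if n <= 0:
        return 0.0
    mx = s0 / n
    my = s1 / n
    mz = s2 / n
    cxx = s3 / n - mx * mx + 1.0 / 12.0
    cyy = s4 / n - my * my + 1.0 / 12.0
    czz = s5 / n - mz * mz + 1.0 / 12.0
    cxy = s6 / n - mx * my
    cxz = s7 / n - mx * mz
    cyz = s8 / n - my * mz
    lam = _max_eig_sym3(cxx, cyy, czz, cxy, cxz, cyz)
    if lam < 0.0:
        lam = 0.0
    return np.sqrt(12.0 * lam)


@njit(cache=False, inline="always")
def _axis_length_cell(volume, M, cid):
    m = M[cid]
    return _axis_from_sums(float(volume[cid]), m[0], m[1], m[2], m[3], m[4],
                           m[5], m[6], m[7], m[8])


@njit(cache=False, inline="always")
def _axis_length_mod(volume, M, cid, x, y, z, sign):
    """Axis length of cell ``cid`` with voxel (x,y,z) added (sign=+1) or
    removed (sign=-1)."""
    m = M[cid]
    n = float(volume[cid]) + sign
    fx = float(x)
    fy = float(y)
    fz = float(z)
    return _axis_from_sums(
        n,
        m[0] + sign * fx, m[1] + sign * fy, m[2] + sign * fz,
        m[3] + sign * fx * fx, m[4] + sign * fy * fy, m[5] + sign * fz * fz,
        m[6] + sign * fx * fy, m[7] + sign * fx * fz, m[8] + sign * fy * fz)


# -------------------------------------------------------------- hamiltonian


@njit(cache=False)
def delta_hamiltonian(grid, ctype, volume, tvol, taxis, M,
                      J, lam_vol, lam_len,
                      fields, mu,
                      offs, periodic,
                      sx, sy, sz, tx, ty, tz):
    """Energy change for copying the cell id at (sx,sy,sz) onto (tx,ty,tz).

    Out-of-lattice neighbors count as medium (cell id 0) on non-periodic
    axes.  ``fields`` is a (k, nx, ny, nz) stack; ``mu`` is (k, n_types).
    """
    nx, ny, nz = grid.shape
    a = grid[sx, sy, sz]
    b = grid[tx, ty, tz]
    if a == b:
        return 0.0
    ta = ctype[a]
    tb = ctype[b]
    dH = 0.0
    # adhesion around the flipped voxel
    for k in range(offs.shape[0]):
        xx = tx + offs[k, 0]
        yy = ty + offs[k, 1]
        zz = tz + offs[k, 2]
        inb = True
        if periodic[0]:
            xx = xx % nx
        elif xx < 0 or xx >= nx:
            inb = False
        if periodic[1]:
            yy = yy % ny
        elif yy < 0 or yy >= ny:
            inb = False
        if periodic[2]:
            zz = zz % nz
        elif zz < 0 or zz >= nz:
            inb = False
        if inb:
            c = grid[xx, yy, zz]
            tc = ctype[c]
        else:
            c = 0
            tc = MEDIUM
        if c != a:
            dH += J[ta, tc]
        if c != b:
            dH -= J[tb, tc]
    # volume constraint (medium carries none)
    if lam_vol > 0.0:
        if a != 0:
            va = float(volume[a])
            Ta = tvol[a]
            dH += lam_vol * ((va + 1.0 - Ta) ** 2 - (va - Ta) ** 2)
        if b != 0:
            vb = float(volume[b])
            Tb = tvol[b]
            dH += lam_vol * ((vb - 1.0 - Tb) ** 2 - (vb - Tb) ** 2)
    # elongation constraint (cells with a target axis only)
    if lam_len > 0.0:
        if a != 0 and taxis[a] > 0.0:
            L0 = _axis_length_cell(volume, M, a)
            L1 = _axis_length_mod(volume, M, a, tx, ty, tz, 1.0)
            La = taxis[a]
            dH += lam_len * ((L1 - La) ** 2 - (L0 - La) ** 2)
        if b != 0 and taxis[b] > 0.0:
            L0 = _axis_length_cell(volume, M, b)
            L1 = _axis_length_mod(volume, M, b, tx, ty, tz, -1.0)
            Lb = taxis[b]
            dH += lam_len * ((L1 - Lb) ** 2 - (L0 - Lb) ** 2)
    # chemotaxis: the moving (non-medium) cell climbs its field gradient;
    # for an extension the cell gains the target voxel, for a retraction
    # (medium source) it loses it, so the sign flips
    for f in range(fields.shape[0]):
        if a != 0:
            m_eff = mu[f, ta]
            dH -= m_eff * (fields[f, tx, ty, tz] - fields[f, sx, sy, sz])
        else:
            m_eff = mu[f, tb]
            dH -= m_eff * (fields[f, sx, sy, sz] - fields[f, tx, ty, tz])
    return dH


@njit(cache=False)
def run_attempts(grid, ctype, volume, tvol, taxis, M, exists, alive,
                 J, lam_vol, lam_len, T,
                 fields, mu, offs_copy, offs_adh, periodic,
                 targ_idx, nbr_choice, rand_u):
    """One batch of Metropolis voxel-copy attempts (in place).

    ``targ_idx`` are flat target-voxel indices, ``nbr_choice`` indexes
    ``offs_copy`` to pick the source neighbor, ``rand_u`` are uniforms.
    Returns the number of accepted copies.
    """
    nx, ny, nz = grid.shape
    accepted = 0
    for i in range(targ_idx.shape[0]):
        t = targ_idx[i]
        tz = t % nz
        ty = (t // nz) % ny
        tx = t // (ny * nz)
        k = nbr_choice[i]
        sx = tx + offs_copy[k, 0]
        sy = ty + offs_copy[k, 1]
        sz = tz + offs_copy[k, 2]
        if periodic[0]:
            sx = sx % nx
        elif sx < 0 or sx >= nx:
            continue
        if periodic[1]:
            sy = sy % ny
        elif sy < 0 or sy >= ny:
            continue
        if periodic[2]:
            sz = sz % nz
        elif sz < 0 or sz >= nz:
            continue
        a = grid[sx, sy, sz]
        b = grid[tx, ty, tz]
        if a == b:
            continue
        if ctype[a] >= DONOR or ctype[b] >= DONOR:
            continue
        dH = delta_hamiltonian(grid, ctype, volume, tvol, taxis, M,
                               J, lam_vol, lam_len, fields, mu,
                               offs_adh, periodic, sx, sy, sz, tx, ty, tz)
        acc = False
        if dH <= 0.0:
            acc = True
        elif T > 0.0 and rand_u[i] < np.exp(-dH / T):
            acc = True
        if acc:
            grid[tx, ty, tz] = a
            fx = float(tx)
            fy = float(ty)
            fz = float(tz)
            if a != 0:
                volume[a] += 1
                M[a, 0] += fx
                M[a, 1] += fy
                M[a, 2] += fz
                M[a, 3] += fx * fx
                M[a, 4] += fy * fy
                M[a, 5] += fz * fz
                M[a, 6] += fx * fy
                M[a, 7] += fx * fz
                M[a, 8] += fy * fz
            if b != 0:
                volume[b] -= 1
                M[b, 0] -= fx
                M[b, 1] -= fy
                M[b, 2] -= fz
                M[b, 3] -= fx * fx
                M[b, 4] -= fy * fy
                M[b, 5] -= fz * fz
                M[b, 6] -= fx * fy
                M[b, 7] -= fx * fz
                M[b, 8] -= fy * fz
                if volume[b] == 0:
                    exists[b] = False
                    alive[b] = False
            accepted += 1
    return accepted


# --------------------------------------------------------------- diffusion


@njit(cache=False)
def diffuse_periodic(c, r, n_sub):
    """Explicit 6-neighbor diffusion with periodic wrap; r = D*dt_sub/h^2."""
    nx, ny, nz = c.shape
    buf = np.empty_like(c)
    src = c
    dst = buf
    for _ in range(n_sub):
        for x in range(nx):
            xm = x - 1 if x > 0 else nx - 1
            xp = x + 1 if x < nx - 1 else 0
            for y in range(ny):
                ym = y - 1 if y > 0 else ny - 1
                yp = y + 1 if y < ny - 1 else 0
                for z in range(nz):
                    zm = z - 1 if z > 0 else nz - 1
                    zp = z + 1 if z < nz - 1 else 0
                    v = src[x, y, z]
                    dst[x, y, z] = v + r * (
                        src[xm, y, z] + src[xp, y, z] + src[x, ym, z]
                        + src[x, yp, z] + src[x, y, zm] + src[x, y, zp]
                        - 6.0 * v)
        src, dst = dst, src
    if src is not c:
        c[:] = src
    return c


@njit(cache=False)
def diffuse_masked(c, mask, dlinks, alinks, dval, aval, r, n_sub):
    """Explicit diffusion restricted to ``mask`` voxels (vascular transport).

    Flux crosses a face only when both voxels are masked.  ``dlinks`` /
    ``alinks`` count virtual donor/acceptor contacts per voxel; each link
    exchanges flux with a clamped value (``dval`` / ``aval``).  Returns the
    net mass inflow through the virtual links (donor + acceptor), for flux
    audits.
    """
    nx, ny, nz = c.shape
    buf = np.empty_like(c)
    src = c
    dst = buf
    boundary_flux = 0.0
    for _ in range(n_sub):
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    if not mask[x, y, z]:
                        dst[x, y, z] = src[x, y, z]
                        continue
                    v = src[x, y, z]
                    acc = 0.0
                    if x > 0 and mask[x - 1, y, z]:
                        acc += src[x - 1, y, z] - v
                    if x < nx - 1 and mask[x + 1, y, z]:
                        acc += src[x + 1, y, z] - v
                    if y > 0 and mask[x, y - 1, z]:
                        acc += src[x, y - 1, z] - v
                    if y < ny - 1 and mask[x, y + 1, z]:
                        acc += src[x, y + 1, z] - v
                    if z > 0 and mask[x, y, z - 1]:
                        acc += src[x, y, z - 1] - v
                    if z < nz - 1 and mask[x, y, z + 1]:
                        acc += src[x, y, z + 1] - v
                    vflux = (dlinks[x, y, z] * (dval - v)
                             + alinks[x, y, z] * (aval - v))
                    acc += vflux
                    boundary_flux += r * vflux
                    dst[x, y, z] = v + r * acc
        src, dst = dst, src
    if src is not c:
        c[:] = src
    return boundary_flux


@njit(cache=False)
def place_blocks(occ, grid, shape_offsets, candidates, n_cells, first_id):
    """Carve ``n_cells`` copies of a voxel shape at random free positions.

    ``candidates`` is a (m, 3) stream of corner positions; a placement is
    accepted when every shape voxel is free.  Returns the number placed.
    """
    placed = 0
    for i in range(candidates.shape[0]):
        if placed >= n_cells:
            break
        x0 = candidates[i, 0]
        y0 = candidates[i, 1]
        z0 = candidates[i, 2]
        ok = True
        for s in range(shape_offsets.shape[0]):
            if occ[x0 + shape_offsets[s, 0], y0 + shape_offsets[s, 1],
                   z0 + shape_offsets[s, 2]]:
                ok = False
                break
        if ok:
            cid = first_id + placed
            for s in range(shape_offsets.shape[0]):
                xx = x0 + shape_offsets[s, 0]
                yy = y0 + shape_offsets[s, 1]
                zz = z0 + shape_offsets[s, 2]
                occ[xx, yy, zz] = True
                grid[xx, yy, zz] = cid
            placed += 1
    return placed
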