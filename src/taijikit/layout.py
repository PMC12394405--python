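"""Canonical skeleton layouts.

The toolkit ships a 32-joint layout (the default annotation scheme: pelvis
root, a four-link spine to the head, seven joints per arm including hand
detail, five per leg including heel and toe) and a reduced 23-joint
kinematic-chain layout obtained by dropping the hand/foot detail joints.
"""

from __future__ import annotations

JOINT_NAMES_32: tuple[str, ...] = (
    "pelvis",          # 0  root
    "spine_01",        # 1
    "spine_02",        # 2
    "spine_03",        # 3
    "chest",           # 4
    "neck",            # 5
    "head",            # 6
    "head_top",        # 7
    "clavicle_l",      # 8
    "shoulder_l",      # 9
    "elbow_l",         # 10
    "wrist_l",         # 11
    "hand_l",          # 12
    "hand_tip_l",      # 13
    "thumb_l",         # 14
    "clavicle_r",      # 15
    "shoulder_r",      # 16
    "elbow_r",         # 17
    "wrist_r",         # 18
    "hand_r",          # 19
    "hand_tip_r",      # 20
    "thumb_r",         # 21
    "hip_l",           # 22
    "knee_l",          # 23
    "ankle_l",         # 24
    "heel_l",          # 25
    "foot_l",          # 26 toe
    "hip_r",           # 27
    "knee_r",          # 28
    "ankle_r",         # 29
    "heel_r",          # 30
    "foot_r",          # 31 toe
)

# parent index per joint; -1 marks the root
PARENTS_32: tuple[int, ...] = (
    -1, 0, 1, 2, 3, 4, 5, 6,
    4, 8, 9, 10, 11, 12, 12,
    4, 15, 16, 17, 18, 19, 19,
    0, 22, 23, 24, 24,
    0, 27, 28, 29, 29,
)

_DETAIL_JOINTS = {
    "head_top", "clavicle_l", "clavicle_r",
    "hand_tip_l", "hand_tip_r", "thumb_l", "thumb_r",
    "heel_l", "heel_r",
}

JOINT_NAMES_23: tuple[str, ...] = tuple(
    n for n in JOINT_NAMES_32 if n not in _DETAIL_JOINTS
)


def joint_index(name: str, names: tuple[str, ...] = JOINT_NAMES_32) -> int:
    return names.index(name)


def skeleton_edges(names: tuple[str, ...] = JOINT_NAMES_32) -> list[tuple[int, int]]:
    """Physical-connectivity edge list (parent, child) for a layout.

    For the reduced layout, each dropped joint's children are re-parented to
    the nearest retained ancestor.
    """
    if names == JOINT_NAMES_32:
        return [(p, c) for c, p in enumerate(PARENTS_32) if p >= 0]
    # reduced layout: walk up PARENTS_32 until a retained joint is found
    keep = set(names)
    idx = {n: i for i, n in enumerate(names)}
    edges: list[tuple[int, int]] = []
    for c32, name in enumerate(JOINT_NAMES_32):
        if name not in keep or PARENTS_32[c32] < 0:
            continue
        p32 = PARENTS_32[c32]
        while p32 >= 0 and JOINT_NAMES_32[p32] not in keep:
            p32 = PARENTS_32[p32]
        if p32 >= 0:
            edges.append((idx[JOINT_NAMES_32[p32]], idx[name]))
    return edges


def parents(names: tuple[str, ...] = JOINT_NAMES_32) -> list[int]:
    """Parent index per joint (-1 for the root) for a layout."""
    par = [-1] * len(names)
    for p, c in skeleton_edges(names):
        par[c] = p
    return par
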