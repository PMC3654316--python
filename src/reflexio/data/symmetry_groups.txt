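# Symmetry registry: rotation matrices act on (h,k,l) column vectors.
# 'rot' lines: 9 integers row-major. 'amb' lines: indexing-ambiguity
# coset representatives (lattice symmetry ops outside the Laue group).

group P1
bravais aP
rot 1 0 0 0 1 0 0 0 1
end

group P2
bravais mP
rot -1 0 0 0 1 0 0 0 -1
rot 1 0 0 0 1 0 0 0 1
end

group C2
bravais mC
rot -1 0 0 0 1 0 0 0 -1
rot 1 0 0 0 1 0 0 0 1
end

group P222
bravais oP
rot -1 0 0 0 -1 0 0 0 1
rot -1 0 0 0 1 0 0 0 -1
rot 1 0 0 0 -1 0 0 0 -1
rot 1 0 0 0 1 0 0 0 1
end

group P212121
bravais oP
rot -1 0 0 0 -1 0 0 0 1
rot -1 0 0 0 1 0 0 0 -1
rot 1 0 0 0 -1 0 0 0 -1
rot 1 0 0 0 1 0 0 0 1
end

group P4
bravais tP
rot -1 0 0 0 -1 0 0 0 1
rot 0 -1 0 1 0 0 0 0 1
rot 0 1 0 -1 0 0 0 0 1
rot 1 0 0 0 1 0 0 0 1
amb 0 1 0 1 0 0 0 0 -1
end

group P422
bravais tP
rot -1 0 0 0 -1 0 0 0 1
rot -1 0 0 0 1 0 0 0 -1
rot 0 -1 0 -1 0 0 0 0 -1
rot 0 -1 0 1 0 0 0 0 1
rot 0 1 0 -1 0 0 0 0 1
rot 0 1 0 1 0 0 0 0 -1
rot 1 0 0 0 -1 0 0 0 -1
rot 1 0 0 0 1 0 0 0 1
end

group P3
bravais hP
rot -1 -1 0 1 0 0 0 0 1
rot 0 1 0 -1 -1 0 0 0 1
rot 1 0 0 0 1 0 0 0 1
amb -1 0 0 0 -1 0 0 0 1
amb 0 1 0 1 0 0 0 0 -1
amb 0 -1 0 -1 0 0 0 0 -1
end

group P321
bravais hP
rot -1 -1 0 0 1 0 0 0 -1
rot -1 -1 0 1 0 0 0 0 1
rot 0 1 0 -1 -1 0 0 0 1
rot 0 1 0 1 0 0 0 0 -1
rot 1 0 0 -1 -1 0 0 0 -1
rot 1 0 0 0 1 0 0 0 1
amb -1 0 0 0 -1 0 0 0 1
end

group P6
bravais hP
rot -1 -1 0 1 0 0 0 0 1
rot -1 0 0 0 -1 0 0 0 1
rot 0 -1 0 1 1 0 0 0 1
rot 0 1 0 -1 -1 0 0 0 1
rot 1 0 0 0 1 0 0 0 1
rot 1 1 0 -1 0 0 0 0 1
amb 0 1 0 1 0 0 0 0 -1
end

group P23
bravais cP
rot -1 0 0 0 -1 0 0 0 1
rot -1 0 0 0 1 0 0 0 -1
rot 0 -1 0 0 0 -1 1 0 0
rot 0 -1 0 0 0 1 -1 0 0
rot 0 0 -1 -1 0 0 0 1 0
rot 0 0 -1 1 0 0 0 -1 0
rot 0 0 1 -1 0 0 0 -1 0
rot 0 0 1 1 0 0 0 1 0
rot 0 1 0 0 0 -1 -1 0 0
rot 0 1 0 0 0 1 1 0 0
rot 1 0 0 0 -1 0 0 0 -1
rot 1 0 0 0 1 0 0 0 1
amb 0 1 0 1 0 0 0 0 -1
end

group I213
bravais cI
rot -1 0 0 0 -1 0 0 0 1
rot -1 0 0 0 1 0 0 0 -1
rot 0 -1 0 0 0 -1 1 0 0
rot 0 -1 0 0 0 1 -1 0 0
rot 0 0 -1 -1 0 0 0 1 0
rot 0 0 -1 1 0 0 0 -1 0
rot 0 0 1 -1 0 0 0 -1 0
rot 0 0 1 1 0 0 0 1 0
rot 0 1 0 0 0 -1 -1 0 0
rot 0 1 0 0 0 1 1 0 0
rot 1 0 0 0 -1 0 0 0 -1
rot 1 0 0 0 1 0 0 0 1
amb 0 1 0 1 0 0 0 0 -1
end
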