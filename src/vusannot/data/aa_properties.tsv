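# Per-residue side-chain property table, version 1.
# atoms: side-chain heavy (non-H) atom count
# hdonors / hacceptors: side-chain hydrogen-bond donor / acceptor heavy atoms
#   (thiol and thioether groups counted as neither; His counted 1/1 at pH 7)
# charge: formal side-chain charge at pH 7
# kd_hydro: Kyte-Doolittle hydropathy
# volume: Zamyatnin residue volume (A^3); deltas equal side-chain deltas
aa	atoms	hdonors	hacceptors	charge	kd_hydro	volume
A	1	0	0	0	1.8	88.6
R	7	3	0	1	-4.5	173.4
N	4	1	1	0	-3.5	114.1
D	4	0	2	-1	-3.5	111.1
C	2	0	0	0	2.5	108.5
Q	5	1	1	0	-3.5	143.8
E	5	0	2	-1	-3.5	138.4
G	0	0	0	0	-0.4	60.1
H	6	1	1	0	-3.2	153.2
I	4	0	0	0	4.5	166.7
L	4	0	0	0	3.8	166.7
K	5	1	0	1	-3.9	168.6
M	4	0	0	0	1.9	162.9
F	7	0	0	0	2.8	189.9
P	3	0	0	0	-1.6	112.7
S	2	1	1	0	-0.8	89.0
T	3	1	1	0	-0.7	116.1
W	10	1	0	0	-0.9	227.8
Y	8	1	1	0	-1.3	193.6
V	3	0	0	0	4.2	140.0
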