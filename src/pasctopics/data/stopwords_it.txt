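# Default Italian stopword list (function words; one token per line)
a
ad
al
alla
alle
allo
agli
anche
ancora
avere
aveva
avevano
ben
che
chi
ci
come
con
cui
da
dal
dalla
dalle
dallo
degli
dei
del
della
delle
dello
dentro
di
dove
due
e
ecco
ed
era
erano
essere
fa
fare
fino
fra
fuori
gli
ha
hanno
ho
il
in
io
la
le
lei
lo
loro
lui
ma
me
mi
mia
mie
mio
ne
nei
nel
nella
nelle
nello
noi
non
nostra
nostre
nostri
nostro
o
ogni
oppure
per
perche
pero
piu
poco
poi
qua
quale
quando
quasi
quella
quelle
quelli
quello
questa
queste
questi
questo
qui
se
sei
sempre
senza
si
sia
siamo
solo
sono
sopra
sotto
sta
stati
stato
stesso
su
sua
sue
sui
sul
sulla
sulle
sullo
suo
te
ti
tra
tu
tua
tue
tuo
tutta
tutte
tutti
tutto
un
una
uno
vi
voi
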