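a
al
algo
ante
como
con
contra
cual
cuando
de
del
desde
donde
durante
e
el
ella
ellas
ellos
en
entre
era
es
esa
ese
esta
este
fue
ha
han
hasta
la
las
le
les
lo
los
más
mi
muy
ni
no
nos
o
otra
otro
para
pero
poco
por
porque
que
quien
se
ser
si
sin
sobre
son
su
sus
también
tan
tanto
tiene
todo
tras
u
un
una
unas
unos
y
ya
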