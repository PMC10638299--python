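# Toy Spanish lexicon: surface<TAB>pos<TAB>lemma
# Deterministic fixture for the annotator contract; covers frequent
# dream-report vocabulary (perception, body, movement, dwelling verbs/nouns)
# with common inflected forms, plus high-frequency function words.
#
# --- ver (to see) ---
ver	VERB	ver
veo	VERB	ver
ves	VERB	ver
ve	VERB	ver
vemos	VERB	ver
veía	VERB	ver
vi	VERB	ver
vio	VERB	ver
visto	VERB	ver
viendo	VERB	ver
# --- ser (to be) ---
ser	VERB	ser
soy	VERB	ser
es	VERB	ser
era	VERB	ser
eran	VERB	ser
fue	VERB	ser
fui	VERB	ser
sido	VERB	ser
# --- estar (to be located/present) ---
estar	VERB	estar
estoy	VERB	estar
está	VERB	estar
estaba	VERB	estar
estaban	VERB	estar
estuve	VERB	estar
estado	VERB	estar
estando	VERB	estar
# --- haber (to have, auxiliary) ---
haber	VERB	haber
he	VERB	haber
ha	VERB	haber
había	VERB	haber
habían	VERB	haber
hay	VERB	haber
hubo	VERB	haber
# --- ir (to go) ---
ir	VERB	ir
voy	VERB	ir
va	VERB	ir
iba	VERB	ir
iban	VERB	ir
yendo	VERB	ir
ido	VERB	ir
# --- hacer (to do/make) ---
hacer	VERB	hacer
hago	VERB	hacer
hace	VERB	hacer
hacía	VERB	hacer
hice	VERB	hacer
hizo	VERB	hacer
hecho	VERB	hacer
haciendo	VERB	hacer
# --- poder (can) ---
poder	VERB	poder
puedo	VERB	poder
puede	VERB	poder
podía	VERB	poder
pude	VERB	poder
pudo	VERB	poder
podido	VERB	poder
# --- dar (to give) ---
dar	VERB	dar
doy	VERB	dar
da	VERB	dar
daba	VERB	dar
di	VERB	dar
dio	VERB	dar
dado	VERB	dar
# --- salir (to leave/exit) ---
salir	VERB	salir
salgo	VERB	salir
sale	VERB	salir
salía	VERB	salir
salí	VERB	salir
salió	VERB	salir
saliendo	VERB	salir
salido	VERB	salir
# --- sentir (to feel) ---
sentir	VERB	sentir
siento	VERB	sentir
siente	VERB	sentir
sentía	VERB	sentir
sentí	VERB	sentir
sintió	VERB	sentir
sintiendo	VERB	sentir
sentido	VERB	sentir
# --- recordar (to remember) ---
recordar	VERB	recordar
recuerdo	VERB	recordar
recuerda	VERB	recordar
recordaba	VERB	recordar
recordé	VERB	recordar
recordado	VERB	recordar
# --- soñar / despertar / dormir / volar / caminar / mirar ---
soñar	VERB	soñar
sueño	NOUN	sueño
sueños	NOUN	sueño
soñé	VERB	soñar
soñaba	VERB	soñar
despertar	VERB	despertar
desperté	VERB	despertar
despierto	ADJ	despierto
dormir	VERB	dormir
dormía	VERB	dormir
dormido	ADJ	dormido
volar	VERB	volar
volaba	VERB	volar
volando	VERB	volar
caminar	VERB	caminar
caminaba	VERB	caminar
caminando	VERB	caminar
mirar	VERB	mirar
miraba	VERB	mirar
miré	VERB	mirar
flotar	VERB	flotar
flotaba	VERB	flotar
intentar	VERB	intentar
intenté	VERB	intentar
intentaba	VERB	intentar
# --- nouns ---
casa	NOUN	casa
casas	NOUN	casa
cuerpo	NOUN	cuerpo
cuerpos	NOUN	cuerpo
habitación	NOUN	habitación
habitaciones	NOUN	habitación
persona	NOUN	persona
personas	NOUN	persona
gente	NOUN	gente
cama	NOUN	cama
puerta	NOUN	puerta
puertas	NOUN	puerta
ventana	NOUN	ventana
calle	NOUN	calle
ciudad	NOUN	ciudad
noche	NOUN	noche
día	NOUN	día
días	NOUN	día
luz	NOUN	luz
luces	NOUN	luz
agua	NOUN	agua
mar	NOUN	mar
cielo	NOUN	cielo
miedo	NOUN	miedo
mano	NOUN	mano
manos	NOUN	mano
cara	NOUN	cara
ojo	NOUN	ojo
ojos	NOUN	ojo
voz	NOUN	voz
madre	NOUN	madre
padre	NOUN	padre
amigo	NOUN	amigo
amiga	NOUN	amigo
amigos	NOUN	amigo
familia	NOUN	familia
lugar	NOUN	lugar
lugares	NOUN	lugar
momento	NOUN	momento
tiempo	NOUN	tiempo
cosa	NOUN	cosa
cosas	NOUN	cosa
techo	NOUN	techo
suelo	NOUN	suelo
pared	NOUN	pared
escalera	NOUN	escalera
espejo	NOUN	espejo
sensación	NOUN	sensación
experiencia	NOUN	experiencia
realidad	NOUN	realidad
# --- adjectives ---
grande	ADJ	grande
grandes	ADJ	grande
pequeño	ADJ	pequeño
pequeña	ADJ	pequeño
oscuro	ADJ	oscuro
oscura	ADJ	oscuro
claro	ADJ	claro
clara	ADJ	claro
extraño	ADJ	extraño
extraña	ADJ	extraño
lúcido	ADJ	lúcido
lúcida	ADJ	lúcido
real	ADJ	real
blanco	ADJ	blanco
blanca	ADJ	blanco
negro	ADJ	negro
negra	ADJ	negro
nuevo	ADJ	nuevo
nueva	ADJ	nuevo
viejo	ADJ	viejo
vieja	ADJ	viejo
alto	ADJ	alto
alta	ADJ	alto
raro	ADJ	raro
rara	ADJ	raro
# --- function words (filtered out of graphs) ---
el	DET	el
la	DET	el
los	DET	el
las	DET	el
un	DET	uno
una	DET	uno
unos	DET	uno
unas	DET	uno
de	ADP	de
del	ADP	de
a	ADP	a
al	ADP	a
en	ADP	en
con	ADP	con
por	ADP	por
para	ADP	para
sin	ADP	sin
sobre	ADP	sobre
hasta	ADP	hasta
desde	ADP	desde
entre	ADP	entre
y	CCONJ	y
o	CCONJ	o
pero	CCONJ	pero
que	SCONJ	que
si	SCONJ	si
cuando	SCONJ	cuando
como	SCONJ	como
porque	SCONJ	porque
no	ADV	no
sí	ADV	sí
muy	ADV	muy
más	ADV	más
menos	ADV	menos
entonces	ADV	entonces
después	ADV	después
luego	ADV	luego
allí	ADV	allí
aquí	ADV	aquí
yo	PRON	yo
tú	PRON	tú
él	PRON	él
ella	PRON	él
nosotros	PRON	nosotros
ellos	PRON	él
me	PRON	yo
te	PRON	tú
se	PRON	se
lo	PRON	él
le	PRON	él
mi	DET	mi
mis	DET	mi
tu	DET	tu
su	DET	su
sus	DET	su
este	DET	este
esta	DET	este
ese	DET	ese
esa	DET	ese
todo	PRON	todo
toda	PRON	todo
algo	PRON	algo
nada	PRON	nada
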