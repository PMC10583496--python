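the	50000
and	26000
a	21000
to	25000
of	16000
i	38000
you	31000
it	20000
in	12000
that	17000
is	10000
was	9000
he	9500
she	7800
they	5600
we	6200
on	5800
with	4400
there	4600
this	5100
his	4300
her	4700
for	5500
are	4200
have	5300
had	3400
not	4800
but	4900
what	6000
all	3300
were	2100
be	6500
at	3300
one	3100
so	5200
out	3600
up	4200
do	5600
me	6900
my	6800
him	3200
them	2300
then	2100
little	1200
see	2600
she's	900
it's	7000
down	1700
can	3300
like	4900
when	2600
get	4300
go	4500
going	2700
got	3200
think	3800
know	7900
just	6400
some	2200
well	4400
very	1400
here	3600
because	1900
looks	450
looking	800
look	2900
water	420
house	640
tree	180
boy	700
girl	680
mother	650
man	2100
woman	580
child	330
children	390
kitchen	160
window	230
over	2400
trying	900
cookie	45
cookies	60
jar	22
dishes	55
sink	48
stool	12
falling	130
ladder	25
cat	190
dog	290
um	1800
uh	3200
hmm	260
er	120
eh	150
mm	210
thing	1900
things	1400
stuff	760
place	1100
something	2500
someone	900
anything	1300
person	560
people	2600
nice	1300
good	5200
old	1400
big	1500
small	420
washing	90
standing	330
outside	560
two	2100
three	1100
time	3600
day	1900
really	3900
always	1800
remember	1200
family	900
friend	650
home	1900
love	2700
beautiful	620
garden	160
school	1100
work	2400
years	1300
lightbulb	4
bulb	14
lamp	30
chair	190
table	420
reaching	70
climbing	40
branch	45
fireman	9
helping	220
happy	1300
wonderful	520
special	640
visit	310
town	480
city	620
lake	130
mountain	90
summer	340
winter	230
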